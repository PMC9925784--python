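"""In-memory volume containers shared by all pipeline stages.

Arrays are indexed ``(x, y, z)`` in the world axis order (scan, lateral,
depth); voxel ``(0, 0, 0)`` is centred at ``origin`` and bounding boxes are
half-open ``[lo, hi)`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


def _as_pitch3(pitch) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(pitch, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3 or np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise DataError(f"voxel pitch must be 1 or 3 positive finite values, got {pitch!r}")
    return tuple(arr)


@dataclass
class IntensityVolume:
    """A 3D grayscale volume on a regular grid.

    Attributes
    ----------
    values : ndarray
        Non-negative intensities, shape ``(nx, ny, nz)``.
    voxel_pitch : tuple of float
        Grid spacing per axis, µm.
    origin : ndarray
        World position of the centre of voxel (0, 0, 0), µm.
    background : float
        Intensity assumed outside the volume (used when sampling past the
        borders, so simulated acquisitions do not see a fake dark edge).
    """

    values: np.ndarray
    voxel_pitch: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    background: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DataError("IntensityVolume requires a 3D array")
        self.voxel_pitch = _as_pitch3(self.voxel_pitch)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise DataError("origin must be a 3-vector")
        if not np.all(np.isfinite(self.values)):
            raise DataError("volume contains non-finite values")
        if self.values.size and float(self.values.min()) < 0:
            raise DataError("volume contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def bbox(self) -> np.ndarray:
        """Half-open world bounding box, shape (3, 2), µm."""
        lo = self.origin - 0.5 * np.asarray(self.voxel_pitch)
        hi = lo + np.asarray(self.shape) * np.asarray(self.voxel_pitch)
        return np.stack([lo, hi], axis=1)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_pitch))

    def world_to_index(self, points):
        """Fractional voxel indices of world points (..., 3) in µm."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) / np.asarray(self.voxel_pitch)

    def index_to_world(self, indices):
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.voxel_pitch) + self.origin


@dataclass
class DeskewedVolume:
    """An orthogonal-grid volume produced by deskewing and/or fusion.

    ``valid`` marks voxels supported by actual raw samples; unsupported
    voxels hold ``background`` and are never blended during fusion.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    valid: np.ndarray | None = None
    background: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DataError("DeskewedVolume requires a 3D array")
        self.spacing = _as_pitch3(self.spacing)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise DataError("valid mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def bbox(self) -> np.ndarray:
        lo = self.origin - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return np.stack([lo, hi], axis=1)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, points):
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) / np.asarray(self.spacing)

    def index_to_world(self, indices):
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing) + self.origin
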