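"""Simulated stage-scanned oblique acquisition: mosaic planning, skewed strip
sampling, light-sheet blur, camera noise and in-plane binning.

A *strip* is one continuous stage scan: the sample moves through the
stationary sheet, and each camera frame records a plane tilted 45° from the
scan axis, yielding the skewed parallelepipedal stack described in
:mod:`lsmosaic.geometry`.  Samples larger than one field of view are covered
by tiling strips laterally and in depth (a *mosaic*).

The simulated sheet thickness enters as a Gaussian blur along the sheet
normal.  Because translating the stage by one slice step moves a fixed tissue
point by ``s·sin(theta)`` along that normal, the blur is applied across the
frame axis with ``sigma = (fwhm/2.355) / (s·sin(theta))`` frames.  Camera
noise is Poisson shot noise on the expected counts plus additive Gaussian
read noise; the default phantom appearance puts ~100 counts at a soma peak,
and read noise defaults to 2 counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError, PlanningError
from .geometry import (
    FWHM_PER_SIGMA,
    MAX_IMAGING_DEPTH_UM,
    AcquisitionGeometry,
    MosaicPreset,
)
from .volumes import IntensityVolume


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise plus Gaussian read noise (counts)."""

    read_sigma: float = 2.0
    enabled: bool = True


@dataclass(frozen=True)
class StripPlan:
    """Placement of one strip within a mosaic."""

    stage_origin: tuple[float, float, float]
    length_um: float
    lateral_index: int
    depth_index: int


@dataclass
class MosaicPlan:
    """Tiling of strips covering a sample bounding box."""

    strips: list[StripPlan]
    overlap_fraction: float
    geometry: AcquisitionGeometry

    @property
    def n_lateral(self) -> int:
        return 1 + max(s.lateral_index for s in self.strips)

    @property
    def n_depth(self) -> int:
        return 1 + max(s.depth_index for s in self.strips)


@dataclass
class RawStrip:
    """One skewed stage-scan stack: frames indexed (k, i, j).

    ``k`` is the frame (stage) index, ``i`` the lateral camera row, ``j`` the
    tilted camera depth column.
    """

    frames: np.ndarray
    geometry: AcquisitionGeometry
    stage_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DataError("RawStrip frames must be 3D (k, i, j)")
        self.stage_origin = np.asarray(self.stage_origin, dtype=float)
        if self.frames.size and float(self.frames.min()) < 0:
            raise DataError("RawStrip frames must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def n_tiles_covering(extent: float, width: float, overlap: float) -> int:
    """Minimal number of tiles of ``width`` covering ``extent`` at ``overlap``."""
    if extent <= width:
        return 1
    return 1 + math.ceil((extent - width) / (width * (1.0 - overlap)))


def plan_mosaic(
    sample_bbox,
    geometry: AcquisitionGeometry,
    overlap_fraction: float = 0.1,
    max_depth_um: float = MAX_IMAGING_DEPTH_UM,
) -> MosaicPlan:
    """Plan strips covering ``sample_bbox`` (shape (3, 2), µm, half-open).

    Strips run along x (the scan axis) and are tiled along y by the frame
    width and along z by the tilt-projected depth coverage.  Strip origins
    are pulled back along x by the shear offset ``n_j·p_j·cos(theta)`` so the
    full bbox is sampled at every depth.  Strips are ordered row-major with
    depth as the outer loop.
    """
    bbox = np.asarray(sample_bbox, dtype=float)
    if bbox.shape != (3, 2) or np.any(bbox[:, 1] <= bbox[:, 0]):
        raise ConfigError("sample_bbox must be (3, 2) with hi > lo per axis")
    if not 0.0 <= overlap_fraction <= 0.5:
        raise ConfigError("overlap_fraction must lie in [0, 0.5]")
    ex, ey, ez = bbox[:, 1] - bbox[:, 0]
    if ez > max_depth_um:
        raise PlanningError(
            f"sample depth {ez:.0f} µm exceeds the maximum imaging depth "
            f"{max_depth_um:.0f} µm"
        )
    width = geometry.frame_width_um
    depth_cov = geometry.depth_coverage_um
    n_lat = n_tiles_covering(ey, width, overlap_fraction)
    n_dep = n_tiles_covering(ez, depth_cov, overlap_fraction)
    shear = geometry.pitch_depth * geometry.frame_shape[1] * geometry.cos_tilt
    # one extra slice step closes the half-open sampling at the far end
    length = ex + shear + geometry.slice_step

    strips: list[StripPlan] = []
    for b in range(n_dep):
        z0 = bbox[2, 0] + b * depth_cov * (1.0 - overlap_fraction)
        for a in range(n_lat):
            y0 = bbox[1, 0] + a * width * (1.0 - overlap_fraction)
            strips.append(
                StripPlan(
                    stage_origin=(bbox[0, 0] - shear, y0, z0),
                    length_um=length,
                    lateral_index=a,
                    depth_index=b,
                )
            )
    return MosaicPlan(strips=strips, overlap_fraction=overlap_fraction, geometry=geometry)


def acquire_strip(
    volume: IntensityVolume,
    geometry: AcquisitionGeometry,
    stage_origin,
    strip_length_um: float,
    seed: int | None = None,
    noise: NoiseModel | None = None,
    chunk_frames: int = 64,
) -> RawStrip:
    """Sample one skewed strip from a phantom intensity volume.

    Frame ``k`` samples the oblique plane through stage position
    ``x0 + k·s``; the world position of sample ``(k, i, j)`` follows the
    geometry's forward model.  Out-of-volume samples read the volume's
    background value.  With ``noise`` enabled a seed is required.
    """
    if noise is not None and noise.enabled and seed is None:
        raise ConfigError("a seed is required when camera noise is enabled")
    stage_origin = np.asarray(stage_origin, dtype=float)
    n_k = max(1, math.ceil(strip_length_um / geometry.slice_step))
    n_i, n_j = geometry.frame_shape

    pitch = np.asarray(volume.voxel_pitch)
    frames = np.empty((n_k, n_i, n_j), dtype=np.float32)
    ii = np.arange(n_i)[:, None]
    jj = np.arange(n_j)[None, :]
    for k0 in range(0, n_k, chunk_frames):
        kk = np.arange(k0, min(k0 + chunk_frames, n_k))[:, None, None]
        x, y, z = geometry.sample_positions(stage_origin, kk, ii[None], jj[None])
        coords = np.stack(
            [
                (np.broadcast_to(x, (len(kk), n_i, n_j)) - volume.origin[0]) / pitch[0],
                (np.broadcast_to(y, (len(kk), n_i, n_j)) - volume.origin[1]) / pitch[1],
                (np.broadcast_to(z, (len(kk), n_i, n_j)) - volume.origin[2]) / pitch[2],
            ]
        )
        frames[k0 : k0 + len(kk)] = ndimage.map_coordinates(
            volume.values.astype(np.float32, copy=False),
            coords,
            order=1,
            mode="constant",
            cval=volume.background,
        )

    sigma_um = geometry.sheet_fwhm / FWHM_PER_SIGMA
    sigma_frames = sigma_um / (geometry.slice_step * geometry.sin_tilt)
    if sigma_frames > 1e-3:
        frames = ndimage.gaussian_filter1d(frames, sigma_frames, axis=0, mode="nearest")

    if noise is not None and noise.enabled:
        rng = np.random.default_rng(seed)
        shot = rng.poisson(np.clip(frames, 0, None)).astype(np.float32)
        frames = shot + rng.normal(0.0, noise.read_sigma, size=frames.shape).astype(
            np.float32
        )
        frames = np.clip(frames, 0, None)

    return RawStrip(frames=frames, geometry=geometry, stage_origin=stage_origin)


def bin_in_plane(strip: RawStrip, preset: MosaicPreset) -> RawStrip:
    """Average-bin raw frames in plane to the preset's effective pitch.

    Binning factors follow the reconciliation rule
    ``f_lateral = round(s·sqrt(2)/p)``, ``f_depth = round(2·s/p)`` (fixed 2×2
    for the highest-resolution preset), which reproduces the published output
    frame sizes 32×45 and 128×186 from 2048² sensors.  Averaging (rather than
    decimation) conserves mean intensity.
    """
    geom = strip.geometry
    f_lat, f_dep = preset.bin_factors(geom.pixel_pitch)
    n_k, n_i, n_j = strip.frames.shape
    m_i, m_j = n_i // f_lat, n_j // f_dep
    if m_i < 1 or m_j < 1:
        raise ConfigError("binning factors exceed the frame size")
    cropped = strip.frames[:, : m_i * f_lat, : m_j * f_dep]
    binned = cropped.reshape(n_k, m_i, f_lat, m_j, f_dep).mean(axis=(2, 4))
    return RawStrip(
        frames=binned.astype(strip.frames.dtype, copy=False),
        geometry=geom.with_binning(f_lat, f_dep),
        stage_origin=strip.stage_origin,
    )
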