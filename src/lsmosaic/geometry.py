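"""Physical sampling geometry of a stage-scanned oblique light-sheet microscope.

In stage-scanned selective-plane illumination the sample is translated through
a stationary light sheet while the camera records frames.  The detection axis
is tilted (45° by default) with respect to the scan direction, so a recorded
stack is a *skewed parallelepiped*: frame index ``k`` advances along the stage
scan axis, camera row ``i`` is lateral, and camera column ``j`` runs along the
tilted detection axis.  All world coordinates are micrometres, right-handed,
with axes

* ``x`` — stage scan direction,
* ``y`` — lateral (camera rows),
* ``z`` — depth into the sample (vertical).

The world position of raw sample ``(k, i, j)`` recorded from stage origin
``(x0, y0, z0)`` is::

    x = x0 + k*s + j*p_j*cos(theta)
    y = y0 + i*p_i
    z = z0 + j*p_j*sin(theta)

with ``s`` the slice step (stage travel per frame), ``p_i``/``p_j`` the
effective lateral/depth pixel pitches and ``theta`` the tilt.  Deskewing onto
an orthogonal grid at 45° produces an axial spacing of ``s*sqrt(2)`` — the
"√2 scaling" that makes the mosaic presets isotropic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ConfigError

#: camera pixel pitch at the sample for the reference instrument (µm/pixel)
DEFAULT_PIXEL_PITCH_UM = 0.3625
#: tilt between detection axis and vertical (degrees)
DEFAULT_TILT_DEG = 45.0
#: light-sheet thickness, full width at half maximum (µm)
DEFAULT_SHEET_FWHM_UM = 8.0
#: sCMOS sensor size (lateral rows, depth columns)
DEFAULT_FRAME_SHAPE = (2048, 2048)
#: tube lens focal length (mm) and objective effective focal length (mm)
DEFAULT_TUBE_FOCAL_MM = 200.0
DEFAULT_EFL_MM = 11.2
#: deepest usable detection range of the instrument (µm)
MAX_IMAGING_DEPTH_UM = 5000.0

#: FWHM of a Gaussian = 2*sqrt(2 ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Sampling model of one stage-scanned acquisition.

    Parameters
    ----------
    pixel_pitch : float
        Camera pixel pitch projected to the sample, µm/pixel.
    tilt_deg : float
        Angle between the detection axis and vertical, degrees, in (0, 90).
    slice_step : float
        Stage travel between consecutive frames, µm.
    sheet_fwhm : float
        Light-sheet thickness (FWHM of the Gaussian profile normal to the
        sheet), µm.
    frame_shape : tuple of int
        ``(n_lateral, n_depth)`` pixels of one (possibly binned) frame.
    bin_factors : tuple of int
        ``(f_lateral, f_depth)`` integer binning already applied to the
        frames; effective pitches are ``pixel_pitch * factor``.
    """

    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM
    tilt_deg: float = DEFAULT_TILT_DEG
    slice_step: float = 11.60
    sheet_fwhm: float = DEFAULT_SHEET_FWHM_UM
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE
    tube_focal_mm: float = DEFAULT_TUBE_FOCAL_MM
    efl_mm: float = DEFAULT_EFL_MM
    bin_factors: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ConfigError("pixel_pitch must be positive")
        if not 0.0 < self.tilt_deg < 90.0:
            raise ConfigError("tilt_deg must lie strictly between 0 and 90")
        if self.slice_step <= 0:
            raise ConfigError("slice_step must be positive")
        if self.sheet_fwhm <= 0:
            raise ConfigError("sheet_fwhm must be positive")
        if any(n < 1 for n in self.frame_shape):
            raise ConfigError("frame_shape entries must be >= 1")
        if any(f < 1 for f in self.bin_factors):
            raise ConfigError("bin_factors must be >= 1")

    # -- derived quantities -------------------------------------------------
    @property
    def tilt_rad(self) -> float:
        return math.radians(self.tilt_deg)

    @property
    def sin_tilt(self) -> float:
        return math.sin(self.tilt_rad)

    @property
    def cos_tilt(self) -> float:
        return math.cos(self.tilt_rad)

    @property
    def magnification(self) -> float:
        """Optical magnification f_tube / EFL (≈17.9 for the defaults)."""
        return self.tube_focal_mm / self.efl_mm

    @property
    def pitch_lateral(self) -> float:
        """Effective lateral pitch after binning, µm."""
        return self.pixel_pitch * self.bin_factors[0]

    @property
    def pitch_depth(self) -> float:
        """Effective pitch along the tilted detection axis after binning, µm."""
        return self.pixel_pitch * self.bin_factors[1]

    @property
    def offset_lateral(self) -> float:
        """Centre offset of a binned lateral pixel w.r.t. the unbinned grid."""
        return 0.5 * (self.bin_factors[0] - 1) * self.pixel_pitch

    @property
    def offset_depth(self) -> float:
        return 0.5 * (self.bin_factors[1] - 1) * self.pixel_pitch

    @property
    def frame_width_um(self) -> float:
        """Lateral field of view of one frame, µm (742.4 for the defaults)."""
        return self.pitch_lateral * self.frame_shape[0]

    @property
    def depth_coverage_um(self) -> float:
        """Vertical depth covered by one frame, µm (tilt projection)."""
        return self.pitch_depth * self.frame_shape[1] * self.sin_tilt

    @property
    def iso_spacing(self) -> float:
        """Orthogonal axial spacing after deskew: slice_step * sqrt(2) at 45°."""
        return self.slice_step * SQRT2

    def sample_positions(self, stage_origin, k, i, j):
        """World position (x, y, z) in µm of raw sample indices ``(k, i, j)``.

        Accepts scalars or broadcastable arrays.  Binned pixels are placed at
        the centre of the pixels they average.
        """
        x0, y0, z0 = stage_origin
        d = j * self.pitch_depth + self.offset_depth
        x = x0 + k * self.slice_step + d * self.cos_tilt
        y = y0 + i * self.pitch_lateral + self.offset_lateral
        z = z0 + d * self.sin_tilt
        return x, y, z

    def raw_indices(self, stage_origin, x, y, z):
        """Inverse of :meth:`sample_positions`: fractional ``(k, i, j)``."""
        x0, y0, z0 = stage_origin
        d = (z - z0) / self.sin_tilt
        j = (d - self.offset_depth) / self.pitch_depth
        k = (x - x0 - d * self.cos_tilt) / self.slice_step
        i = (y - y0 - self.offset_lateral) / self.pitch_lateral
        return k, i, j

    def with_binning(self, f_lateral: int, f_depth: int) -> "AcquisitionGeometry":
        """Geometry describing frames binned by the given integer factors."""
        if f_lateral < 1 or f_depth < 1:
            raise ConfigError("binning factors must be >= 1")
        if self.bin_factors != (1, 1):
            raise ConfigError("geometry is already binned")
        n_i, n_j = self.frame_shape
        return replace(
            self,
            frame_shape=(n_i // f_lateral, n_j // f_depth),
            bin_factors=(f_lateral, f_depth),
        )


@dataclass(frozen=True)
class MosaicPreset:
    """A named multiscale acquisition preset (slice step + binning rule).

    The three presets trade speed for resolution: the slice step ``s`` sets
    the post-deskew isotropic spacing ``g = s*sqrt(2)``, and raw frames are
    integer-binned in plane to match: ``f_lateral = round(s*sqrt(2)/p)`` and
    ``f_depth = round(2*s/p)`` (the depth axis projects by a further factor
    ``1/sin 45° = sqrt(2)``).  The highest-resolution preset instead uses a
    fixed 2×2 binning, giving near-isotropic 0.725 × 0.5127 × 0.5127 µm
    voxels.
    """

    name: str
    slice_step: float
    fixed_bin: tuple[int, int] | None = None

    @property
    def iso_spacing(self) -> float:
        """Isotropic grid spacing after deskew, µm (``s * sqrt(2)``)."""
        return self.slice_step * SQRT2

    def bin_factors(self, pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM) -> tuple[int, int]:
        """Integer in-plane binning factors ``(f_lateral, f_depth)``."""
        if self.fixed_bin is not None:
            return self.fixed_bin
        f_lat = round(self.iso_spacing / pixel_pitch)
        f_dep = round(2.0 * self.slice_step / pixel_pitch)
        if f_lat < 1 or f_dep < 1:
            raise ConfigError(
                f"preset {self.name!r}: binning factor below 1 for pitch {pixel_pitch}"
            )
        return f_lat, f_dep

    def geometry(self, **overrides) -> AcquisitionGeometry:
        """Unbinned acquisition geometry with this preset's slice step."""
        return AcquisitionGeometry(slice_step=self.slice_step, **overrides)

    def binned_geometry(self, **overrides) -> AcquisitionGeometry:
        geom = self.geometry(**overrides)
        return geom.with_binning(*self.bin_factors(geom.pixel_pitch))

    def deskewed_spacing(
        self, pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM
    ) -> tuple[float, float, float]:
        """Output grid spacing (x, y, z) in µm after deskewing this preset.

        The scan and depth axes land on ``g = s*sqrt(2)``.  The lateral pitch
        is snapped to ``g`` when it already matches to within 5% (the
        isotropic presets); otherwise it is kept, which yields the
        near-isotropic ``(0.5127, 0.725, 0.5127)`` µm grid of the
        highest-resolution preset.
        """
        g = self.iso_spacing
        f_lat, f_dep = self.bin_factors(pixel_pitch)
        p_lat = pixel_pitch * f_lat
        p_dep_z = pixel_pitch * f_dep * math.sin(math.radians(DEFAULT_TILT_DEG))
        gy = g if abs(p_lat - g) <= 0.05 * g else p_lat
        gz = g if abs(p_dep_z - g) <= 0.05 * g else p_dep_z
        return (g, gy, gz)


MOSAIC16 = MosaicPreset("Mosaic16", slice_step=11.60)
MOSAIC4 = MosaicPreset("Mosaic4", slice_step=2.90)
MOSAIC0_5 = MosaicPreset("Mosaic0_5", slice_step=DEFAULT_PIXEL_PITCH_UM, fixed_bin=(2, 2))

PRESETS: dict[str, MosaicPreset] = {p.name: p for p in (MOSAIC16, MOSAIC4, MOSAIC0_5)}


def get_preset(name: str) -> MosaicPreset:
    try:
        return PRESETS[name]
    except KeyError:
        known = ", ".join(PRESETS)
        raise ConfigError(f"unknown mosaic preset {name!r}; known presets: {known}") from None
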