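"""Reconstruction of skewed raw strips into orthogonal fused volumes.

Stages: shear *deskew* of each strip onto an orthogonal (near-)isotropic
grid, pairwise tile registration by phase correlation, global least-squares
consistency of the pairwise shifts, linear-blend *fusion*, and maximum
intensity projections / reslicing for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import connected_components
from scipy.sparse import coo_matrix

from .acquisition import RawStrip
from .errors import ConfigError, DataError
from .geometry import SQRT2
from .volumes import DeskewedVolume


# ---------------------------------------------------------------------------
# deskew
# ---------------------------------------------------------------------------

def default_deskew_spacing(strip: RawStrip) -> tuple[float, float, float]:
    """Output grid spacing for a strip: ``g = s*sqrt(2)`` on scan and depth
    axes; the lateral pitch is snapped to ``g`` when within 5% (isotropic
    presets), otherwise kept as-is (the near-isotropic high-res preset)."""
    geom = strip.geometry
    g = geom.slice_step * SQRT2
    p_lat = geom.pitch_lateral
    p_dep_z = geom.pitch_depth * geom.sin_tilt
    gy = g if abs(p_lat - g) <= 0.05 * g else p_lat
    gz = g if abs(p_dep_z - g) <= 0.05 * g else p_dep_z
    return (g, gy, gz)


def deskew(
    strip: RawStrip,
    spacing=None,
    order: int = 1,
    chunk_planes: int = 64,
) -> DeskewedVolume:
    """Resample a skewed strip onto an orthogonal grid.

    The world position of each raw sample follows the acquisition forward
    model; output voxels are filled by interpolation (trilinear by default,
    ``order=0`` for label volumes) and voxels with no raw support are marked
    invalid and hold the background value.  The output box is the tight world
    bounding box of the sampled parallelepiped.
    """
    geom = strip.geometry
    if not 0.0 < geom.tilt_deg < 90.0:
        raise ConfigError("tilt angle must lie strictly between 0 and 90 degrees")
    if spacing is None:
        spacing = default_deskew_spacing(strip)
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ConfigError("deskew spacing must be positive")

    n_k, n_i, n_j = strip.frames.shape
    s = geom.slice_step
    # world position of raw sample (0,0,0) and extents of the parallelepiped
    ox, oy, oz = geom.sample_positions(strip.stage_origin, 0, 0, 0)
    ext = np.array(
        [
            (n_k - 1) * s + (n_j - 1) * geom.pitch_depth * geom.cos_tilt,
            (n_i - 1) * geom.pitch_lateral,
            (n_j - 1) * geom.pitch_depth * geom.sin_tilt,
        ]
    )
    shape = tuple(int(np.floor(e / sp)) + 1 for e, sp in zip(ext, spacing))
    origin = np.array([ox, oy, oz])

    values = np.empty(shape, dtype=np.float32)
    valid = np.empty(shape, dtype=bool)
    yy = origin[1] + np.arange(shape[1]) * spacing[1]
    zz = origin[2] + np.arange(shape[2]) * spacing[2]
    frames = strip.frames.astype(np.float32, copy=False)
    background = float(np.min(frames)) if frames.size else 0.0
    for x0 in range(0, shape[0], chunk_planes):
        xs = origin[0] + np.arange(x0, min(x0 + chunk_planes, shape[0])) * spacing[0]
        X = xs[:, None, None]
        Y = yy[None, :, None]
        Z = zz[None, None, :]
        k, i, j = geom.raw_indices(strip.stage_origin, X, Y, Z)
        blk = (len(xs), shape[1], shape[2])
        coords = np.stack(
            [
                np.broadcast_to(k, blk),
                np.broadcast_to(i, blk),
                np.broadcast_to(j, blk),
            ]
        )
        sub_valid = (
            (coords[0] >= 0)
            & (coords[0] <= n_k - 1)
            & (coords[1] >= 0)
            & (coords[1] <= n_i - 1)
            & (coords[2] >= 0)
            & (coords[2] <= n_j - 1)
        )
        sub = ndimage.map_coordinates(
            frames, coords, order=order, mode="constant", cval=background
        )
        sub[~sub_valid] = background
        values[x0 : x0 + len(xs)] = sub
        valid[x0 : x0 + len(xs)] = sub_valid

    return DeskewedVolume(
        values=values,
        spacing=tuple(spacing),
        origin=origin,
        valid=valid,
        background=background,
    )


# ---------------------------------------------------------------------------
# tile registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftEstimate:
    """Refined relative offset (origin_b − origin_a) for one tile pair."""

    pair: tuple[int, int]
    shift_um: tuple[float, float, float]
    score: float
    degenerate: bool = False


def _phase_correlation(
    ref: np.ndarray,
    mov: np.ndarray,
    max_shift: tuple[int, int, int],
    subpixel: bool = False,
) -> tuple[np.ndarray, float]:
    """Translation ``d`` (voxels) such that ``mov`` ≈ ``ref`` shifted by ``d``
    (``np.roll(ref, d)`` aligns with ``mov``), from the argmax of the inverse
    FFT of the normalised cross-power spectrum, searched within ±max_shift.

    A separable Hann window suppresses the spurious edge correlations of the
    non-periodic crops, which otherwise bias small shifts toward zero."""
    window = np.ones(ref.shape, dtype=np.float32)
    for ax, n in enumerate(ref.shape):
        h = np.hanning(n).astype(np.float32)
        shape = [1, 1, 1]
        shape[ax] = n
        window = window * h.reshape(shape)
    fa = np.fft.fftn((ref - ref.mean()) * window)
    fb = np.fft.fftn((mov - mov.mean()) * window)
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    corr = np.fft.ifftn(cross / mag).real

    # restrict the peak search to displacements within ±max_shift
    grids = np.meshgrid(
        *[np.minimum(np.arange(n), n - np.arange(n)) for n in corr.shape],
        indexing="ij",
    )
    within = np.ones_like(corr, dtype=bool)
    for g, m in zip(grids, max_shift):
        within &= g <= m
    corr_masked = np.where(within, corr, -np.inf)
    peak = np.unravel_index(np.argmax(corr_masked), corr.shape)
    score = float(np.clip(corr[peak], 0.0, 1.0))

    shift = np.array(
        [p if p <= n // 2 else p - n for p, n in zip(peak, corr.shape)], dtype=float
    )
    if subpixel:
        for ax, (p, n) in enumerate(zip(peak, corr.shape)):
            c0 = corr[peak]
            idx_m = list(peak)
            idx_p = list(peak)
            idx_m[ax] = (p - 1) % n
            idx_p[ax] = (p + 1) % n
            cm, cp = corr[tuple(idx_m)], corr[tuple(idx_p)]
            denom = c0 - 0.5 * (cm + cp)
            if denom > 0:
                shift[ax] += 0.25 * (cp - cm) / denom
    return shift, score


def phase_correlate(
    tile_a: DeskewedVolume,
    tile_b: DeskewedVolume,
    pair: tuple[int, int] = (0, 1),
    nominal_shift_um=None,
    max_dev_fraction: float = 0.25,
    min_overlap_vox: int = 32,
    subpixel: bool = False,
) -> ShiftEstimate:
    """Refine the relative offset of two tiles by phase correlation.

    The nominal shift defaults to the difference of tile origins; the two
    tiles' nominal overlap region is cross-correlated and the peak searched
    within ±``max_dev_fraction`` of the overlap size.  A degenerate (e.g.
    constant) overlap yields a zero-confidence estimate at the nominal shift.
    """
    sa = np.asarray(tile_a.spacing)
    if not np.allclose(sa, tile_b.spacing, rtol=1e-6):
        raise DataError("tiles must share the same spacing")
    if nominal_shift_um is None:
        nominal_shift_um = tile_b.origin - tile_a.origin
    nominal_shift_um = np.asarray(nominal_shift_um, dtype=float)

    # overlap box in world coordinates, assuming the nominal shift
    b_origin = tile_a.origin + nominal_shift_um
    lo = np.maximum(tile_a.origin, b_origin)
    hi = np.minimum(
        tile_a.origin + np.asarray(tile_a.shape) * sa,
        b_origin + np.asarray(tile_b.shape) * sa,
    )
    n_overlap = np.floor((hi - lo) / sa).astype(int)
    if np.any(n_overlap < min_overlap_vox):
        raise DataError(
            f"tiles {pair} share less than {min_overlap_vox} voxels of nominal "
            f"overlap per axis (got {tuple(n_overlap)})"
        )
    a_lo = np.round((lo - tile_a.origin) / sa).astype(int)
    b_lo = np.round((lo - b_origin) / sa).astype(int)
    crop_a = tile_a.values[tuple(slice(l, l + n) for l, n in zip(a_lo, n_overlap))]
    crop_b = tile_b.values[tuple(slice(l, l + n) for l, n in zip(b_lo, n_overlap))]

    if float(crop_a.std()) == 0.0 or float(crop_b.std()) == 0.0:
        return ShiftEstimate(
            pair=pair, shift_um=tuple(nominal_shift_um), score=0.0, degenerate=True
        )
    max_shift = tuple(max(1, int(max_dev_fraction * n)) for n in n_overlap)
    resid_vox, score = _phase_correlation(crop_a, crop_b, max_shift, subpixel=subpixel)
    # content displaced by +d voxels relative to nominal means tile_b's true
    # origin sits at nominal − d·spacing
    shift = nominal_shift_um - resid_vox * sa
    return ShiftEstimate(pair=pair, shift_um=tuple(shift), score=score)


@dataclass
class TileLayout:
    """Globally consistent per-tile world offsets."""

    offsets_um: np.ndarray  # (n_tiles, 3)
    anchor: int
    residuals_um: np.ndarray  # (n_estimates, 3)

    @property
    def residual_norm(self) -> float:
        if self.residuals_um.size == 0:
            return 0.0
        return float(np.sqrt((self.residuals_um**2).sum(axis=1)).max())


def globalize_shifts(
    estimates,
    n_tiles: int,
    nominal_offsets,
    anchor: int = 0,
) -> TileLayout:
    """Least-squares tile offsets from pairwise shift estimates.

    Each estimate contributes ``t_b − t_a = shift`` weighted by its
    correlation score; the anchor tile is pinned to its nominal offset.
    Raises on a disconnected pair graph (listing the components).
    """
    nominal = np.asarray(nominal_offsets, dtype=float)
    if nominal.shape != (n_tiles, 3):
        raise ConfigError("nominal_offsets must have shape (n_tiles, 3)")
    estimates = list(estimates)
    if n_tiles == 1 or not estimates:
        if n_tiles > 1:
            raise DataError("no pairwise estimates for a multi-tile layout")
        return TileLayout(
            offsets_um=nominal.copy(), anchor=anchor, residuals_um=np.zeros((0, 3))
        )

    rows, cols, vals = [], [], []
    for e_idx, est in enumerate(estimates):
        a, b = est.pair
        rows += [e_idx, e_idx]
        cols += [a, b]
        vals += [1.0, 1.0]
    graph = coo_matrix(
        (vals, (rows, cols)), shape=(len(estimates), n_tiles)
    )
    adjacency = (graph.T @ graph).tocsr()
    n_comp, labels = connected_components(adjacency, directed=False)
    if n_comp > 1:
        comps = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        raise DataError(f"tile pair graph is disconnected; components: {comps}")

    weights = np.array([max(est.score, 1e-6) for est in estimates])
    a_mat = np.zeros((len(estimates) + 1, n_tiles))
    b_vec = np.zeros((len(estimates) + 1, 3))
    for e_idx, est in enumerate(estimates):
        a, b = est.pair
        w = weights[e_idx]
        a_mat[e_idx, a] = -w
        a_mat[e_idx, b] = w
        b_vec[e_idx] = w * np.asarray(est.shift_um)
    big = 1e6 * max(weights.max(), 1.0)
    a_mat[-1, anchor] = big
    b_vec[-1] = big * nominal[anchor]

    sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    residuals = np.stack(
        [
            sol[est.pair[1]] - sol[est.pair[0]] - np.asarray(est.shift_um)
            for est in estimates
        ]
    )
    # pin the anchor exactly to the nominal stage origin
    sol = sol + (nominal[anchor] - sol[anchor])
    return TileLayout(offsets_um=sol, anchor=anchor, residuals_um=residuals)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def _ramp_weight(shape: tuple[int, int, int]) -> np.ndarray:
    """Separable triangular weight, ~0 at tile edges, 1 at the centre."""
    ws = []
    for n in shape:
        x = (np.arange(n) + 0.5) / n  # in (0, 1)
        ws.append(np.minimum(x, 1.0 - x) * 2.0)
    w = ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]
    return np.maximum(w, 1e-9).astype(np.float32)


def fuse(tiles, layout: TileLayout | None = None) -> DeskewedVolume:
    """Blend tiles into one volume with edge-ramped linear weights.

    Weights ramp to zero at tile edges and are renormalised to sum to one
    wherever at least one tile contributes, so constant tiles fuse to the
    same constant and every fused voxel is a convex combination of tile
    values.  Tile offsets are snapped to the common voxel grid.
    """
    tiles = list(tiles)
    if not tiles:
        raise ConfigError("fuse requires at least one tile")
    spacing = np.asarray(tiles[0].spacing)
    for t in tiles[1:]:
        if not np.allclose(spacing, t.spacing, rtol=1e-6):
            raise DataError("all tiles must share the same spacing")
    if layout is None:
        offsets = np.stack([t.origin for t in tiles])
    else:
        offsets = np.asarray(layout.offsets_um, dtype=float)

    lo = np.min(offsets, axis=0)
    hi = np.max(offsets + np.array([t.shape for t in tiles]) * spacing, axis=0)
    shape = tuple(np.ceil((hi - lo) / spacing - 0.5).astype(int))
    num = np.zeros(shape, dtype=np.float64)
    den = np.zeros(shape, dtype=np.float64)
    background = tiles[0].background

    for t_idx, tile in enumerate(tiles):
        off_vox = np.round((offsets[t_idx] - lo) / spacing).astype(int)
        w = _ramp_weight(tile.shape)
        if tile.valid is not None:
            w = w * tile.valid
        sl = tuple(slice(o, o + n) for o, n in zip(off_vox, tile.shape))
        num[sl] += w * tile.values
        den[sl] += w

    covered = den > 0
    fused = np.full(shape, background, dtype=np.float32)
    fused[covered] = (num[covered] / den[covered]).astype(np.float32)
    return DeskewedVolume(
        values=fused,
        spacing=tuple(spacing),
        origin=lo,
        valid=covered,
        background=background,
    )


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def mip_slabs(volume: DeskewedVolume, axis: int, slab_um: float) -> np.ndarray:
    """Maximum-intensity projections over consecutive slabs along ``axis``.

    Returns an array of 2D projections, one per slab of thickness
    ``slab_um`` (the last slab may be thinner).
    """
    sp = volume.spacing[axis]
    if slab_um < sp:
        raise ConfigError("slab thickness must be at least one voxel spacing")
    per_slab = int(slab_um // sp)
    n = volume.shape[axis]
    mips = []
    for start in range(0, n, per_slab):
        sl = [slice(None)] * 3
        sl[axis] = slice(start, min(start + per_slab, n))
        mips.append(volume.values[tuple(sl)].max(axis=axis))
    return np.stack(mips)


def reslice(volume: DeskewedVolume, axes: tuple[int, int, int]) -> DeskewedVolume:
    """Permute volume axes without interpolation (e.g. to a YZ view)."""
    if sorted(axes) != [0, 1, 2]:
        raise ConfigError("axes must be a permutation of (0, 1, 2)")
    return DeskewedVolume(
        values=np.transpose(volume.values, axes),
        spacing=tuple(volume.spacing[a] for a in axes),
        origin=volume.origin[list(axes)],
        valid=None if volume.valid is None else np.transpose(volume.valid, axes),
        background=volume.background,
    )
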