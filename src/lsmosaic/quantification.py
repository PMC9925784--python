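"""Layer-wise 3D cell quantification.

Mirrors the quantitative histology workflow applied to reconstructed
high-resolution volumes: background removal with a morphological top-hat,
3D soma segmentation (multiscale Laplacian-of-Gaussian seeding + seeded
watershed), a strict size filter at 125 µm³, assignment of segments to
manually drawn cortical layers by *full containment*, pooled per-layer
density estimation in cells/mm³, and the empirical overcount correction
(automated pipelines overcount by ~17% on average after size filtering,
because large somata with internal intensity structure split into multiple
segments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import feature, filters, measure, morphology, segmentation

from .errors import ConfigError, DataError

#: minimum segment volume retained by the size filter (µm³, strict ">")
DEFAULT_MIN_VOLUME_UM3 = 125.0
#: average overcount rate of the automated segmentation after size filtering
DEFAULT_OVERCOUNT_RATE = 0.17

UNASSIGNED = "UNASSIGNED"
EXCLUDED = "EXCLUDED"

SEGMENT_COLUMNS = (
    "segment_id",
    "x_um",
    "y_um",
    "z_um",
    "volume_um3",
    "voxels",
    "layer",
)


@dataclass
class SegmentationResult:
    """Detected 3D segments: itemised table plus the label image.

    ``table`` columns follow :data:`SEGMENT_COLUMNS`; centroids are world
    coordinates in µm; ``volume_um3 = voxels × voxel volume``.
    """

    table: pd.DataFrame
    label_image: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


def filter_morphology(
    values: np.ndarray, radius_um: float, spacing
) -> np.ndarray:
    """White top-hat with a ball structuring element of the given radius.

    Removes background varying on scales larger than somata while preserving
    soma-sized peaks; output is non-negative and a constant input maps to
    zero.  The ball radius is expressed in voxels using the mean grid
    spacing, so the grid should be close to isotropic (the deskewed output
    is).  The ball is applied as a decomposed footprint sequence, which keeps
    the filter fast on large volumes.
    """
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    if radius_um < spacing.max():
        raise ConfigError("filter radius must be at least one voxel spacing")
    r_vox = max(1, int(round(radius_um / spacing.mean())))
    footprint = morphology.ball(r_vox, decomposition="sequence")
    return morphology.white_tophat(np.ascontiguousarray(values), footprint=footprint)


@dataclass(frozen=True)
class BlobParams:
    """Parameters of the LoG + watershed soma segmenter (µm units)."""

    min_sigma_um: float = 1.5
    max_sigma_um: float = 4.0
    num_sigma: int = 5
    threshold_mode: str = "otsu"  # or "absolute" / "relative"
    threshold: float | None = None
    log_threshold_rel: float = 0.1
    log_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.min_sigma_um <= 0 or self.max_sigma_um < self.min_sigma_um:
            raise ConfigError("require 0 < min_sigma_um <= max_sigma_um")
        if self.threshold_mode not in ("otsu", "absolute", "relative"):
            raise ConfigError(
                "threshold_mode must be 'otsu', 'absolute' or 'relative'"
            )
        if self.threshold_mode in ("absolute", "relative") and self.threshold is None:
            raise ConfigError(f"{self.threshold_mode} threshold_mode requires a threshold")


def segment_blobs(
    values: np.ndarray,
    spacing,
    params: BlobParams | None = None,
    origin=(0.0, 0.0, 0.0),
) -> SegmentationResult:
    """Segment bright 3D blobs (somata) in a filtered volume.

    Seeds come from multiscale Laplacian-of-Gaussian detection between
    ``min_sigma_um`` and ``max_sigma_um``; the foreground mask is an
    automatic (Otsu), absolute, or peak-relative threshold on the filtered
    volume (``relative`` thresholds at ``threshold × max`` — useful when the
    volume is dominated by background, where Otsu sits low enough to let
    blur tails of neighbouring cells bridge); touching
    somata are split by a seeded watershed on the inverted intensity.
    Foreground components that received no seed are kept as single segments,
    so isolated faint cells are not dropped.  An empty foreground yields an
    empty table, not an error.
    """
    params = params or BlobParams()
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    origin = np.asarray(origin, dtype=float)
    values = np.asarray(values)

    if params.threshold_mode == "otsu":
        finite = values[np.isfinite(values)]
        if finite.size == 0 or float(finite.max()) == float(finite.min()):
            return _empty_result(values.shape, spacing, origin)
        thresh = float(filters.threshold_otsu(finite))
    elif params.threshold_mode == "relative":
        thresh = float(params.threshold) * float(values.max())
    else:
        thresh = float(params.threshold)
    mask = values > thresh
    if not mask.any():
        return _empty_result(values.shape, spacing, origin)

    vmax = float(values.max())
    sigmas_vox_min = params.min_sigma_um / spacing
    sigmas_vox_max = params.max_sigma_um / spacing
    blobs = feature.blob_log(
        values.astype(np.float32) / vmax,
        min_sigma=sigmas_vox_min,
        max_sigma=sigmas_vox_max,
        num_sigma=params.num_sigma,
        threshold=None,
        threshold_rel=params.log_threshold_rel,
        overlap=params.log_overlap,
        exclude_border=False,
    )
    markers = np.zeros(values.shape, dtype=np.int32)
    n_seeds = 0
    for b in blobs:
        idx = tuple(int(round(c)) for c in b[:3])
        if mask[idx]:
            n_seeds += 1
            markers[idx] = n_seeds

    if n_seeds:
        labels = segmentation.watershed(-values, markers=markers, mask=mask)
    else:
        labels = np.zeros(values.shape, dtype=np.int32)
    # foreground left unclaimed by any seed: keep connected components
    leftover = mask & (labels == 0)
    if leftover.any():
        extra, n_extra = ndimage.label(leftover)
        labels = labels + np.where(extra > 0, extra + n_seeds, 0).astype(labels.dtype)

    return _result_from_labels(labels, spacing, origin)


def _empty_result(shape, spacing, origin) -> SegmentationResult:
    return SegmentationResult(
        table=pd.DataFrame(columns=SEGMENT_COLUMNS),
        label_image=np.zeros(shape, dtype=np.int32),
        spacing=tuple(spacing),
        origin=origin,
    )


def _result_from_labels(labels, spacing, origin) -> SegmentationResult:
    voxel_volume = float(np.prod(spacing))
    props = measure.regionprops(labels)
    rows = []
    for p in props:
        centroid = origin + np.asarray(p.centroid) * spacing
        rows.append(
            (p.label, centroid[0], centroid[1], centroid[2],
             p.area * voxel_volume, int(p.area), UNASSIGNED)
        )
    table = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return SegmentationResult(
        table=table, label_image=labels, spacing=tuple(spacing), origin=origin
    )


def filter_segments(
    table: pd.DataFrame, min_volume_um3: float = DEFAULT_MIN_VOLUME_UM3
) -> pd.DataFrame:
    """Retain segments with volume strictly greater than ``min_volume_um3``.

    The boundary is exclusive: a segment of exactly the threshold volume is
    removed.
    """
    return table[table["volume_um3"] > min_volume_um3].reset_index(drop=True)


def assign_layers(
    result: SegmentationResult,
    layer_labels: np.ndarray,
    layer_names,
    excluded_mask: np.ndarray | None = None,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Assign each segment to the layer that fully contains it.

    A segment belongs to layer L only if *every* voxel of the segment
    carries label L.  Segments straddling two layers (or reaching label 0)
    are marked ``UNASSIGNED``; segments overlapping the excluded (damaged)
    region, or touching the outer volume border when ``exclude_border`` is
    set, are marked ``EXCLUDED``.  Both groups are dropped from density
    counts.
    """
    labels_img = result.label_image
    if layer_labels.shape != labels_img.shape:
        raise DataError("layer label volume shape does not match the segmentation")
    if excluded_mask is not None and excluded_mask.shape != labels_img.shape:
        raise DataError("excluded mask shape does not match the segmentation")
    layer_names = list(layer_names)
    table = result.table.copy()
    if table.empty:
        return table

    assignments = []
    shape = np.asarray(labels_img.shape)
    for p in measure.regionprops(labels_img):
        sl = p.slice
        seg_mask = labels_img[sl] == p.label
        if exclude_border:
            lo = np.array([s.start for s in sl])
            hi = np.array([s.stop for s in sl])
            touches = np.any(lo == 0) or np.any(hi == shape)
            if touches and _touches_border(seg_mask, lo, hi, shape):
                assignments.append((p.label, EXCLUDED))
                continue
        if excluded_mask is not None and bool(excluded_mask[sl][seg_mask].any()):
            assignments.append((p.label, EXCLUDED))
            continue
        under = np.unique(layer_labels[sl][seg_mask])
        if len(under) == 1 and under[0] > 0:
            assignments.append((p.label, layer_names[int(under[0]) - 1]))
        else:
            assignments.append((p.label, UNASSIGNED))

    assign_df = pd.DataFrame(assignments, columns=["segment_id", "layer"])
    table = table.drop(columns=["layer"]).merge(assign_df, on="segment_id", how="left")
    table["layer"] = table["layer"].fillna(UNASSIGNED)
    return table


def _touches_border(seg_mask, lo, hi, shape) -> bool:
    for ax in range(3):
        if lo[ax] == 0:
            face = [slice(None)] * 3
            face[ax] = 0
            if seg_mask[tuple(face)].any():
                return True
        if hi[ax] == shape[ax]:
            face = [slice(None)] * 3
            face[ax] = -1
            if seg_mask[tuple(face)].any():
                return True
    return False


@dataclass
class LayerDensityReport:
    """Per-layer pooled counts, volumes and (corrected) densities.

    ``table`` columns: layer, count, volume_mm3, density_per_mm3,
    corrected_per_mm3.  Counts are pooled over all disconnected patches of
    each layer; corrected densities apply the overcount correction
    ``ceil(density × (1 − r))``.
    """

    table: pd.DataFrame
    overcount_rate: float

    @property
    def total_density(self) -> float:
        tot_count = self.table["count"].sum()
        tot_vol = self.table["volume_mm3"].sum()
        return float(tot_count / tot_vol) if tot_vol > 0 else float("nan")


def compute_densities(
    table: pd.DataFrame,
    layer_labels: np.ndarray,
    layer_names,
    voxel_volume_um3: float,
    excluded_mask: np.ndarray | None = None,
    overcount_rate: float = DEFAULT_OVERCOUNT_RATE,
) -> LayerDensityReport:
    """Pooled per-layer densities in cells/mm³.

    Layer volume is the labelled voxel count × voxel volume with excluded
    regions subtracted; counts pool every assigned segment of a layer across
    all of its disconnected patches.  A layer with zero measured volume but
    a non-zero count is an error.
    """
    layer_names = list(layer_names)
    rows = []
    for li, name in enumerate(layer_names):
        mask = layer_labels == li + 1
        if excluded_mask is not None:
            mask = mask & ~excluded_mask
        volume_mm3 = float(mask.sum()) * voxel_volume_um3 * 1e-9
        count = int((table["layer"] == name).sum())
        if volume_mm3 == 0 and count > 0:
            raise DataError(f"layer {name!r} has segments but zero measured volume")
        density = count / volume_mm3 if volume_mm3 > 0 else 0.0
        rows.append(
            (name, count, volume_mm3, density, correct_density(density, overcount_rate))
        )
    report = pd.DataFrame(
        rows, columns=["layer", "count", "volume_mm3", "density_per_mm3", "corrected_per_mm3"]
    )
    return LayerDensityReport(table=report, overcount_rate=overcount_rate)


def correct_density(density_per_mm3: float, rate: float = DEFAULT_OVERCOUNT_RATE) -> int:
    """Overcount-corrected density: ``ceil(density × (1 − rate))``.

    The ceiling is the rounding rule consistent with published corrected
    values (81,903 → 67,980 at rate 0.17, etc.).
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError("overcount rate must lie in [0, 1)")
    return math.ceil(density_per_mm3 * (1.0 - rate))


@dataclass(frozen=True)
class ShrinkageRecord:
    """Surface-area change of one tissue slice through clearing."""

    slice_id: str
    area_before_mm2: float
    area_after_mm2: float

    @property
    def reduction_percent(self) -> float:
        """Positive = shrinkage, negative = expansion."""
        return 100.0 * (1.0 - self.area_after_mm2 / self.area_before_mm2)


def measure_shrinkage(
    polygon_before, polygon_after, slice_id: str = ""
) -> ShrinkageRecord:
    """Area reduction of a slice outline before vs after clearing.

    Vertices are (x, y) pairs in mm; areas come from the shoelace formula
    (via shapely).  Self-intersecting outlines are rejected.
    """
    areas = []
    for verts, tag in ((polygon_before, "before"), (polygon_after, "after")):
        poly = Polygon(verts)
        if not poly.is_valid:
            raise DataError(f"{tag} outline is not a simple polygon")
        if poly.area <= 0:
            raise DataError(f"{tag} outline has non-positive area")
        areas.append(poly.area)
    return ShrinkageRecord(slice_id, areas[0], areas[1])


def summarize_shrinkage(records) -> float:
    """Mean percent area reduction over slices."""
    records = list(records)
    if not records:
        raise DataError("no shrinkage records to summarise")
    return float(np.mean([r.reduction_percent for r in records]))
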