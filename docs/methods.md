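# Methods

This note records the models behind `lsmosaic`, the defaults that matter,
and the choices made where the design was genuinely open.

## Sampling geometry

The forward model places raw sample `(k, i, j)` of a strip at world position
`(x0 + k·s + j·p_j·cosθ, y0 + i·p_i, z0 + j·p_j·sinθ)` with slice step `s`,
effective pixel pitches `p_i, p_j` (camera pitch × binning factor) and tilt
`θ` (45° default, any value in (0°, 90°) supported). Binned pixels sit at the
centre of the pixels they average, which keeps a directly simulated binned
acquisition geometrically identical to fine acquisition followed by
averaging. The same formulas, inverted, drive the deskew resampling, so
forward geometry and reconstruction cannot drift apart.

Constants for the reference instrument: camera pitch 0.3625 µm/pixel at the
sample, 2048² sensor (742.4 µm lateral field of view), tube focal length
200 mm over an 11.2 mm effective focal length (magnification ≈17.9), maximum
imaging depth 5 mm, light-sheet thickness 8 µm FWHM. The three mosaic
presets are `Mosaic16` (s = 11.60 µm), `Mosaic4` (s = 2.90 µm) and
`Mosaic0_5` (s = 0.3625 µm). We take the high-resolution slice step as
exactly the pixel pitch, 0.3625 µm (it is sometimes quoted rounded to
0.363 µm), which is the value consistent with the 0.5127 µm = 0.3625·√2
deskewed pixel.

**Binning rule.** The in-plane downsampling that matches the slice step is
`f_lateral = round(s·√2/p)` and `f_depth = round(2s/p)`; `Mosaic0_5` uses a
fixed 2 × 2. Output dimensions are `floor(N/f)` with averaging (not
decimation), which conserves mean intensity exactly. This rule reproduces
both published binned frame sizes (32 × 45 and 128 × 186 from 2048²), which
is how we reconcile the nominal "16×/4× downsampling" descriptions with the
printed dimensions. We fix the printed "32 × 45" order as depth × lateral.

**Deskew spacing.** Scan and depth axes land on `g = s·√2`. The lateral
pitch is snapped to `g` when within 5% (both isotropic presets; the Mosaic4
lateral pitch 3.99 µm differs from g = 4.10 µm by 2.8% and is resampled to
the isotropic grid), otherwise kept — giving the near-isotropic
(0.5127, 0.725, 0.5127) µm grid of `Mosaic0_5`.

**Sheet blur.** The Gaussian sheet profile (σ = FWHM/2.355 ≈ 3.40 µm) acts
along the sheet normal. Because advancing the stage by one slice step moves
a fixed tissue point `s·sinθ` along that normal, the blur is applied across
the frame axis with `σ_frames = σ/(s·sinθ)` after ideal plane sampling; this
is exact up to the discreteness of the frame sampling (σ_frames ≈ 0.41
frames for the coarsest preset, where the blur is anyway far below the
voxel size).

**Noise.** Camera counts are Poisson(expected counts) plus Gaussian read
noise (σ = 2 counts default). The default phantom appearance puts ~100
counts at a soma peak and 10 at background, so the simulated SNR is
realistic for a fast overview scan. Noise, blur and out-of-volume background
reads are all configurable; geometry tests switch noise off.

**Mosaic planning.** Strips run along the scan axis and tile laterally by
the frame width and in depth by the tilt-projected frame depth
(`p_j·N_j·sinθ`), with 10% default overlap (a declared default — real
stitching overlaps are rarely reported). Strip origins are pulled back along
x by the shear offset `N_j·p_j·cosθ`, and one extra slice step is appended,
so the requested box is fully sampled at every depth. A sample deeper than
the 5 mm instrument limit is a planning error.

## Phantom

The phantom is a slab of layers stacked along z in anatomical order
(I, II, IIIa, IIIb, IV, V, VI, WM). Default densities (cells/mm³) follow
measurements in human occipital cortex: 60,000 (I), 71,599 (II), 66,884
(IIIa), 82,712 (IIIb), 97,529 (IV), 88,781 (V), 81,904 (VI); no white-matter
density is available, so a low placeholder of 5,000 is used. Layer
thicknesses are nominal anatomical values for a ≈2 mm cortical ribbon
(120/120/200/250/280/250/350 µm + 300 µm WM) and are freely configurable —
the densities, not the thicknesses, are the quantity of interest.

Cells are drawn per layer as a homogeneous Poisson process (count ~
Poisson(density × layer volume), centres uniform in the layer). The RNG
stream is split per layer by layer index, so draws are reproducible and
stable under profile edits. Soma radii follow a truncated normal (redraw
until positive), default mean 4 µm, sd 1 µm; soma sizes are not reported for
the reference data, so these are stand-ins chosen to bracket the
conventional 125 µm³ size filter (≈ radius 3.1 µm). An optional hard-core
mode rejects centres whose soma surface would come within a minimum gap of
an already placed soma (dart throwing with a configurable attempt budget),
and optional margins keep centres away from volume faces and layer
boundaries — test phantoms built this way make exact-count comparisons
meaningful, because no ground-truth cell straddles a border that the
counting rules would have to exclude.

Rendering places each soma as a sphere with one of three intensity
profiles: `uniform`; `shell` (bright cytoplasmic rim, dimmer core); or
`nucleolus` (dim cytoplasm at 0.65 peak, dimmer nucleus at 0.35, one bright
nucleolus at 1.3 — forced onto its nearest voxel so sub-voxel nucleoli do
not vanish). Overlapping somata add on a constant background. The
`nucleolus` mode exists because real large neurons show exactly this
internal contrast, which is what makes automated segmenters split them —
the splitting-bias property test uses it.

What the generator does **not** emulate: vasculature and tears, layer
curvature (boundaries are flat planes), spatially varying staining
efficiency, scattering-induced depth attenuation, and anisotropic optical
PSF beyond the sheet profile. Passing tests therefore demonstrate the
correctness of the geometry, reconstruction and counting machinery — not
segmentation robustness on real tissue.

## Reconstruction

Deskewing resamples trilinearly (nearest-neighbour available for label
volumes) onto the orthogonal grid anchored at the parallelepiped's minimum
world corner, half-open voxel convention; voxels without raw support carry
the background value and a validity mask, so fusion never blends
unsupported voxels.

Pairwise tile registration is phase correlation over the nominal overlap:
normalised cross-power spectrum, inverse FFT, peak search restricted to
±25% of the overlap size around the nominal shift (avoiding spurious global
maxima far from the stage position), optional parabolic sub-voxel
refinement. A separable Hann window is applied first — without it the edge
mismatch of non-periodic crops biases small shifts toward zero by exactly
one voxel, which a reference implementation without windowing reproduces.
Constant overlaps yield a zero-confidence estimate at the nominal shift.
Global consistency is a score-weighted linear least squares over all
pairwise estimates with the anchor tile pinned to its nominal stage origin;
a disconnected pair graph is an error listing the components.

Fusion blends tiles with separable triangular weights that ramp to zero at
tile edges and renormalise to one wherever any tile contributes; fused
voxels are convex combinations of tile values, identical overlapping data
fuse idempotently, and tile offsets are snapped to the common voxel grid
(sub-voxel placement is deliberately out of scope — residuals after global
optimisation are below one voxel). 16-bit export uses a linear rescale with
the scale/offset recorded in the JSON sidecar.

## Quantification

The segmentation chain mirrors a commercial blob-finder pipeline whose
algorithm is undisclosed; it is re-specified here as standard components
with all parameters exposed:

1. **Top-hat filter**: white top-hat with a ball of configurable radius
   (default 6 µm), applied as a decomposed footprint sequence for speed;
   removes background structure larger than somata, maps constants to zero.
   The ball radius is expressed in voxels of the mean spacing, so the grid
   should be near-isotropic (the deskewed output is).
2. **Blob segmentation**: multiscale Laplacian-of-Gaussian seeds between
   1.5 and 4 µm (per-axis sigmas in voxel units, relative threshold 0.1,
   overlap pruning 0.5), foreground by Otsu (or absolute) threshold, seeded
   watershed on inverted intensity to split touching somata. Foreground
   components without any seed are kept as single segments so faint
   isolated cells are not dropped. Empty foreground is an empty table, not
   an error.
3. **Size filter**: keep volumes strictly greater than 125 µm³ — the
   boundary is exclusive, matching the "larger than" convention.
4. **Layer assignment**: a segment belongs to a layer only if *every* voxel
   carries that label; segments touching two layers are UNASSIGNED,
   segments overlapping the excluded (damaged-region) mask or touching the
   outer volume border are EXCLUDED. Both are dropped from density counts.
   Border exclusion guards against partial objects; layer volumes are
   measured from the label volume itself (labelled voxels × voxel volume,
   excluded regions subtracted).
5. **Densities**: counts pooled over all disconnected patches of a layer,
   divided by the layer volume in mm³. The pooled density equals the
   volume-weighted mean of patch densities by construction.
6. **Overcount correction**: `corrected = ceil(density × (1 − r))`,
   r = 0.17 default. The ceiling is the unique simple rounding rule
   consistent with all three published corrected values
   (81,903→67,980; 77,807→64,580; 86,579→71,861).

Tissue shrinkage is measured from before/after slice outlines (simple
polygons, vertices in mm) via shoelace areas; reduction is
`100·(1 − after/before)`, negative values (expansion) are reported, not
rejected.

## Counting-frame validation

Volumes are divided into 100 × 100 µm half-open grid cells (partial edge
cells flagged and never sampled); 10 planes and 5 distinct ROIs per plane
are drawn without replacement from a seeded generator. Two counting rules
operate on 2D disc footprints (for segmentations, the equal-area disc of
the segment's voxels in the plane):

* **as-published** — count objects fully inside the ROI or intersecting its
  left and/or lower border. Applied over a full tiling this rule
  double-counts objects spanning an interior grid corner (an object over a
  corner is counted by the cell above-left, the cell below-right *and* the
  corner cell); it is retained verbatim as a mode for fidelity.
* **strict** (default) — the unbiased counting frame: count objects that
  intersect the ROI but touch neither the *full extended line* through the
  right border nor the top border segment. The extension matters: excluding
  only the right border *segment* is still not exactly unbiased for objects
  near a grid corner that miss the diagonal cell. With the extended-line
  rule every interior object is counted exactly once over a tiling (proved
  by the column-then-row argument for convex footprints smaller than a grid
  cell, and property-tested over seeded configurations), and strict counts
  are a subset of as-published counts on every ROI.

Overcount summaries report the mean of per-ROI percent differences
`100·(auto − ref)/ref` as the headline (the ratio-of-totals variant is
reported alongside, since "average overcount" is ambiguous between the
two), with zero-reference ROIs tallied separately.

## Problem sizes and numerical choices

The parameter-recovery experiment uses a 0.2 × 0.2 × 0.12 mm two-layer
phantom (layer IIIb/IV-like densities 82,712 and 97,529 cells/mm³,
~440 cells) rendered at 0.6 µm pitch and imaged with the high-resolution
preset in a single strip — sized so the full chain runs in about two
minutes on one CPU while still containing hundreds of cells per layer. Its
radius law is tightened to mean 4.2 µm, sd 0.2 µm so that no ground-truth
soma sits near the 125 µm³ filter boundary (the smallest drawn soma is
≈200 µm³); with the default law a tail cell below ≈3.1 µm radius would be
correctly filtered out of the automated count but still present in the
ground truth, making exact-count comparison meaningless. Density errors are
reported against the *realised* phantom density (count/volume), since the
Poisson draw itself fluctuates a few percent around the nominal density at
this volume. The experiment's segmentation uses the peak-relative
foreground threshold (0.3 × max) rather than Otsu: on a volume dominated by
background, Otsu settles low enough that sheet-blur tails of neighbouring
somata bridge across the 8 µm gap and segments balloon to twice their
geometric volume, occasionally merging pairs or reaching the crop border;
the relative threshold keeps segment volumes close to the geometric soma
volume. Otsu remains the default for data whose intensity scale is unknown.

Point-source round trips use scaled-down strips (256² raw frames) with
sources spread along the strip axis; localisation uses an
intensity-weighted centroid in a window sized to cover the sheet-blur tail.
Interpolation is trilinear everywhere except label volumes
(nearest-neighbour). Tie-breaks: argmax takes the first maximum in C order;
the size filter is strictly exclusive at the boundary; degenerate
(constant) phase-correlation overlaps return the nominal shift with zero
confidence rather than failing.

## Known limitations

* Fusion ignores sub-voxel components of the optimised layout.
* The morphological filter assumes a near-isotropic grid.
* The blob segmenter is tuned for convex, roughly spherical somata; heavily
  elongated cells (or the `nucleolus` appearance) split, which is the
  documented overcount mechanism rather than a defect to be hidden.
* Exact-count recovery is demonstrated for hard-core-separated phantoms;
  at realistic packing with touching somata the pipeline overcounts, and
  the overcount-correction stage exists precisely for that regime.
* The simulator models single-view acquisition only; dual-view acquisition
  and joint deconvolution are out of scope.
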