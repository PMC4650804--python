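# Methods

This note documents the models, parameter choices and numerical conventions
behind `vesselseg`: what the pipeline assumes, what the synthetic phantom
does and does not emulate, and where design latitude was resolved by
implementation choices.

## Coordinate conventions

Volumes are `(slice, row, col)` with the vessel axis along the slice axis
and isotropic voxels (size in µm supplied by the caller; TIFF carries no
reliable spacing metadata). Trans-axial coordinates are `(x = col, y = row)`
voxel centres. Unwrapped images put arc position on rows and radial offset
on cols, with column `inner_margin` exactly on the lumen spline and columns
increasing outward; in this frame the elastic lamellae are near-vertical
lines and all texture filtering operates "along the vertical axis" (across
rows). Rows sample a closed curve, so every row-direction operation
(morphological opening, surface smoothing, the geodesic closure term) is
periodic. Label codes are 0 background/paraffin, 1 lumen, 2 media,
3 adventitia, 4 pore.

Arc positions are anchored at the point where each slice's lumen spline
crosses angle 0 from its centroid, so row *r* refers to (approximately) the
same angular position in every slice; without this, cross-slice surface
smoothing would mix unrelated angles.

## Pipeline stages and defaults

None of the stage parameters below are prescribed by the protocol this
package implements; each default is an implementation choice, exposed in
`SegmentConfig`/`RunConfig` and recorded here.

- **Axial bilateral filter** — window 7 voxels, spatial σ 1.5 voxels, range
  σ estimated robustly as the MAD-based SD of axial first differences.
  Filtering only along the axis preserves in-plane edges completely.
- **Lumen detection** — marching-squares contour at the wall threshold
  (per-slice Otsu by default); the lumen is the smallest closed contour
  enclosing the centre hint (default: centroid of the below-threshold
  interior). A hint that does not sit in a below-threshold region is an
  error — it distinguishes a solid disk from a vessel.
- **Lumen spline** — closed periodic smoothing spline (FITPACK), smoothing
  budget 0.5 per contour point. More smoothing attenuates genuine luminal
  ripple; less lets contour jitter through. The spline is the unwrap anchor
  only; the reported lumen edge is sub-voxel refined (below).
- **Unwrap** — 256 arc samples per slice (a fixed count so all slices share
  a row grid), inner margin 8 voxels, outer depth 64 voxels, bilinear
  sampling. Row spacing equals `perimeter/256` ≈ 1 voxel at the spline; the
  unwrapped frame under-samples the wall tangentially at larger radii by a
  factor `(R_lumen + d)/R_lumen` (≈ 2.3 at the outer wall edge of the
  default phantom). Area measurements are therefore never taken in the
  unwrapped frame; labels are re-wrapped first.
- **Wall threshold** — Otsu on the unwrapped slice, or a fixed value.
- **Vertical opening** — line element of length 13, periodic across rows.
  The outermost lamella is exactly vertical in the unwrapped frame and
  survives any length; residual adventitial speckle must be shorter than
  the element to be removed, and 13 rows proved sufficient at the phantom's
  fibre texture. Island removal threshold: 4 px (8-connected), retained at
  exactly the threshold.
- **Edge model** — Gaussian mixture (2 components by default) on the
  candidate boundary positions `xe + 1`, with deterministic k-quantile mean
  initialisation, uniform initial weights, ≤ 200 EM iterations, tolerance
  1e-8. `xe + 1` is read as the first pixel outside the wall per row — the
  candidate boundary position one step outward from the outermost retained
  wall pixel. The dominant mean is the mean of the largest-weight
  component, which presumes boundary rows are the majority; the opening
  length above is chosen to keep contaminated rows a clear minority.
  Closeness tolerance: 2 dominant-component SDs.
- **Weight image** — base 1.0 everywhere; −0.5 inside the initial
  thresholded mask; +2.0 at candidate pixels within the tolerance of the
  dominant mean (penalty first, bonus on top, clipped at 0).
- **Geodesic boundary** — exact minimisation of
  `Σ (W_max − W) + λ Σ|Δc|` with `|Δc| ≤ d_max = 2` per row, free
  endpoints, and periodic closure penalised by the same λ term;
  λ defaults to `0.5·edge_bonus/d_max`. Solved by dynamic programming over
  (start column, current column) states, which is exact for this
  row-layered graph; ties break toward the smaller column everywhere so the
  output is deterministic. On instances small enough to enumerate, the
  returned cost equals the global minimum to 1e-9.
- **Surface smoothing** — Gaussian, σ 3 rows × 2 slices, periodic in rows,
  replicated at the stack ends.
- **Sub-voxel refinement** (on by default) — integer column estimates carry
  a threshold-dependent placement bias (a mask thresholded below the edge
  midpoint extends systematically outward). All three interfaces are
  therefore refined to local mid-level intensity crossings: the
  media–adventitia boundary and the lumen edge on the unwrapped slice
  around the traced path / the spline column, and the outer wall edge on a
  tangentially averaged profile (Gaussian over rows, σ 4), taking the
  outermost falling crossing so interior texture dips cannot trigger early.
  Rows without a crossing fall back to the half-voxel face convention
  (boundary on the face between the outermost wall pixel and the first
  outside pixel).
- **Outer wall edge** — the outermost thresholded pixel per row is a sparse
  point process on the fibrous adventitia texture and its gaps bias the
  estimate only inward; a rolling-max envelope over a 5-slice × 9-row
  window precedes the refinement and smoothing. The outer edge is also
  constrained to lie at least 1 voxel outside the media–adventitia
  boundary.
- **Failure handling** — slices where lumen detection or the spline fit
  fails are flagged for manual review, left unlabelled, and excluded from
  morphometry; their boundary rows are filled from the nearest successful
  slice only to keep the 3D smoother well-posed.

## Morphometry

Thickness is measured along the unwrap normals (column differences between
the refined interfaces), not as Euclidean nearest-boundary distance; the
per-slice statistic is the mean over rows, and group dispersion is across
slices (mean ± SEM, Welch two-sample test). Slices within one tomogram are
spatially autocorrelated, so these p-values are anti-conservative; the
caveat is embedded in the output rather than corrected. CSAs are voxel
counts × voxel-size²; the class areas of a slice always sum exactly to the
slice area because the label volume is a partition. Axial length is
reported rounded to the nearest micron (450 slices × 0.75 µm → 338 µm).
`ray_thickness` provides an independent ray-cast measurement route used to
validate the morphometry on ground-truth labels.

Pores are voxels inside the wall's filled hull (per-slice closing with a
5-voxel disk, holes filled, the 4-voxel-dilated lumen excluded) darker than
`paraffin_mean − max(k·SD, 0.15·(paraffin_mean − darkest_in_hull))`, in
26-connected components of ≥ 10 voxels; k = 3 by default. The noise floor
term needs explanation: within a collagen-textured wall the local
background around a pore is *raised* by blurred fibre brightness, so the
pore's surface level set hugs the paraffin level itself; a shallow floor
(15% of the darkest-voxel depth) recovers noiseless pore volumes to a few
percent, while under noise the k·SD term dominates and detection is
deliberately conservative (cores only). Pore count is robust in both
regimes; calibrated volume recovery is only claimed for low-noise data.

The luminal surface map is `r(arc, slice)` from the refined lumen edge;
roughness statistics are computed on residuals after removing each slice's
mean radius, so a sinusoidal ripple of amplitude *a* has RMS `a/√2` and
axially oriented ripple appears as circumferential variance far exceeding
axial variance.

## The phantom

The generator renders the tissue architecture the pipeline targets: an
air-dark lumen (grey 10), paraffin background (60), interlamellar tissue
(100), elastic lamellae (180), adventitial collagen fibres (160) and pores
(25), at 0.75 µm voxels, followed by Gaussian PSF blur (σ 0.8 voxels) and
additive Gaussian noise (SD 8 by default, ≈ 7% of the lamella–paraffin
contrast). The ordering pore < paraffin < interlamellar is enforced; the
rest is configurable. Ground truth (labels, boundary radii, analytic
per-slice CSAs and thicknesses) is computed from the pre-blur geometry —
blur and noise are measurement effects, not anatomy.

Geometry: 5 lamellae of 3 voxels separated by 3-voxel gaps (the innermost
pinned to the lumen edge, the outermost to the media–adventitia boundary,
interior ones carrying sinusoidal waviness with random phases), a 25-voxel
adventitia, optional per-slice centre drift, and an axially coherent
sinusoidal luminal ripple (amplitude 3 voxels, wavelength 60 voxels along
the circumference) that propagates through the wall, as a deforming wall
would. The lamellar count and pore size range are not anatomically
calibrated — they are plausible placeholders chosen to exercise the
pipeline.

Two phantom design points matter for interpreting the tests:

- **Adventitial texture** is short fibre segments with random *3D*
  orientation, ~2 voxels thick, at 30% volume density, drawn in a slightly
  dilated annulus and clipped back so coverage stays uniform up to the
  layer boundaries. In-plane segments would unwrap into long vertical bands
  and defeat the opening cue at any useful density — and real adventitial
  bundles run predominantly out of the trans-axial plane, appearing as
  short disordered marks per slice. The 30% density keeps the blurred
  texture below the vertical-percolation regime in which the thresholded
  adventitia becomes a solid block.
- **Pores** are spheres with radii uniform in [3, 5] voxels placed in the
  adventitia with light rejection sampling (≥ r₁+r₂+1 separation, 200
  attempts, overlaps merge if placement fails), so the generated count is
  normally exact and the analytic volume `Σ 4πr³/3` matches the voxelised
  truth.

What the phantom does *not* emulate: beam hardening, ring artefacts,
phase-contrast fringes, intensity inhomogeneity, non-circular or branching
lumens, smooth-muscle microstructure, and any skin-like geometry. Passing
the phantom suite therefore demonstrates that the algorithmic chain is
correct and calibrated under controlled degradation (blur + additive
noise), not that it is robust to every artefact of real tomograms — real
data may still need the flag-and-review path and parameter adjustment.

## Validation suite

`tests/` covers each operation against independent oracles (exhaustive
intra-class-variance minimisation for Otsu, shift-composition morphology,
BFS flood fill, naive scans, brute-force path enumeration, analytic
geometry) plus end-to-end recovery: on twenty 256×256×64 phantoms with
noise at 15% of the lamella–paraffin contrast, both layers are recovered
with Dice ≥ 0.95 and median boundary radial error well under 2 voxels; on
noiseless phantoms, ray-cast thickness and voxel-counted CSA match the
analytic truth within 5% and 2% respectively, 20 pores are recovered with
exact count and volume within 15%, and a blind pressurised/unpressurised
comparison reproduces the expected remodelling directions (larger lumen
CSA; thinner media and adventitia; smaller adventitial CSA; smaller pore
volume). `scripts/acceptance.py` recomputes all of these from scratch;
problem sizes (20 phantoms of 256×256×64, 100 12×12 geodesic instances)
were chosen to make the whole run complete in a few minutes on one CPU
while keeping every claim statistically meaningful.

## Known limitations

- Single-lumen, star-shaped cross-sections only; no bifurcations, no
  deformable slice-to-slice registration.
- The dominant-GMM-component rule fails if residual adventitial features
  survive the opening in most rows of a slice; the opening length is the
  guard, and such slices surface as boundary outliers rather than being
  detected intrinsically.
- Welch p-values across slices ignore axial autocorrelation (flagged in the
  output).
- Pore volume under noise is a lower bound by construction.
- The unwrap transform assumes outward normals do not cross within the
  sampled depth; strongly concave lumens flag the affected rows but the
  resampled intensities there are still distorted.
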