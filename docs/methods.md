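# Methods

This note documents the models, conventions and parameter choices behind
faquant, in the order data flows through the pipeline. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic scenes

The generator stands in for the raw microscopy a lab workflow would
consume. It emulates the statistical structure the analysis assumes —
not the optics.

**Geometry.** The cell is a centred disk (radius 0.45 × min image
dimension). The perinuclear (inner) compartment is defined by the same
rule the analysis uses — pixels whose Euclidean distance to the cell
edge is ≥ `region_fraction` (default 0.5) of the maximum — so generated
compartment assignments and recovered ones agree by construction.
Adhesions are rotated ellipses with areas drawn uniformly from
`area_range` (default 0.5–4 µm², inside the 0.2–6 µm² analysis band) and
major/minor ratios from `axis_ratio_range` (default 1.5–4, the elongated
puncta morphology). Placement is rejection sampling: an object must lie
entirely inside its assigned compartment and keep a 2-px halo from
neighbours; 10,000 failed attempts raise a capacity error.

**Intensity model.** Each object is a flat plateau, not a Gaussian
bump: in-object values occupy the band [0.70, 1.80] × `amplitude` above
`background_level`, with the spatial arrangement given by rank-uniform
texture (ranks of a smoothed Gaussian field, mapped to an exact uniform
grid). Edges are anti-aliased by 4×4-subsample coverage; pixels with
coverage ≥ 0.5 form the ground-truth mask, partially covered rim pixels
ramp down smoothly. Two properties motivated this over a Gaussian
radial profile:

1. the measured (thresholded) area of a plateau object is insensitive
   to where in the background/object gap the threshold lands, so
   segmentation recovers the true area to within a few percent even for
   0.5 µm² objects — a Gaussian profile makes area a steep function of
   threshold;
2. the band width fixes the within-object signal SD at
   s ≈ 0.32 × amplitude, which is what lets realistic per-object
   correlations survive sensor noise (next paragraph).

**Correlation calibration.** Within each object the first channel's
standardized texture is `u`; the second channel is the exact-sample-
correlation mixture `z = c·u + √(1−c²)·w⊥` (w⊥ Gram-Schmidt
orthogonalized against u), scaled to the same mean and SD. Additive
sensor noise of SD σ attenuates the measured pixel-wise correlation by
f² = s²/(s²+σ²) (both channels carry independent noise of equal σ), so
the generator sets c = ρ/f², clipped to [−1, 1]. The expected *measured*
r of the noisy channels then equals the requested ρ — the quantity the
ground truth must pin down for the colocalization stage to be testable.
With the default band, ρ up to ≈ 0.92 is achievable at SNR 10; beyond
the clip the generator delivers the closest achievable correlation.
Measured recovery error across ρ ∈ {0, 0.3, 0.6, 0.9} is reported by
the acceptance script (≲ 0.005 in practice, against a ±0.05 contract).

**Noise.** Additive Gaussian with σ = amplitude / snr, plus optional
Poisson resampling of the clean intensities (`poisson=True`); the image
is clipped at 0 (with the default background = 100 and σ = 100 the clip
is inactive inside objects). No PSF, no photobleaching, no camera gain
model — passing tests therefore show correctness of the *quantification*
given blob-like structures, not robustness to optical artefacts.

**Displaced-septin mode.** `inner_offset_um` renders the second
channel's inner-compartment blobs displaced by that distance in a random
direction instead of in place; within the first-channel mask the second
channel is then background + noise (truth ρ recorded as 0). This builds
scenes where peripheral adhesions colocalize and perinuclear ones do
not, the qualitative contrast the region-resolved analysis must resolve.

**Pixel sizes.** 0.11 µm/px default for TIRF-like FA scenes (100×-class
sampling), 0.325 µm/px for wide-field-like clearance scenes (20×-class);
both configurable.

**Time-lapses, clearance, tracks.** Time-lapse objects are constant
plateaus present exactly during [appear, disappear] frames; truth
lifetime = frames present × dt. Clearance scenes use *rectangular*
holes so the cleared pixel area is exact by construction, plus disjoint
nuclei discs (radius 6 px). Tracks follow straight, uniform-random-walk
or von Mises biased-walk step models with fixed step length.

## Image operations

- **Background subtraction**: grayscale opening with a disk (rolling-ball
  equivalent), output clipped at 0. Function default radius 50 px; the
  FA segmentation config uses 20 px, which exceeds the minor width of
  any in-band FA at 0.11 µm/px while keeping the opening fast.
- **Median filter**: square (2r+1)² neighbourhood, reflect edges,
  default r = 1.
- **Otsu**: one histogram bin per grey level for integer images, 256
  bins over [min, max] for float. Foreground is *strictly above* the
  threshold everywhere in the package (fixes the ±1-px-rim ambiguity).
  Between-class-variance ties (empty histogram gaps) are resolved to the
  first maximizer; every tie member separates the classes identically.
  A constant image raises `NoContrastError`.
- **Connected components**: default 8-connectivity (the Analyze
  Particles convention).

## Adhesion morphometrics and colocalization

Segmentation pipeline: subtract background → median → Otsu → label →
discard components with area ≤ 0.20 µm² or ≥ 6 µm² (both bounds
exclusive on the kept side; the filter is exact by construction).
Axes come from the second-moment (Legendre) ellipse;
roundness = 4·area/(π·major²), clamped to (0, 1]. Objects touching the
image border are kept but flagged. Per-object Pearson r uses the
object's pixels only; objects in which either channel is constant are
reported NaN and excluded from binning. Random binning shuffles with a
caller-supplied seed, averages consecutive groups of `bin_size`
(default 10) and drops the remainder.

The inner/outer partition replaces a manually drawn perinuclear
boundary with the edge-distance rule (fraction 0.5 default);
user-supplied masks can be passed instead to mimic manual ROIs. An
object's compartment is decided by its centroid pixel.

## Profiles

Scans sample bilinear interpolation at unit-pixel spacing; `width`
(odd) parallel offset lines are averaged. Normalization is min-max,
(i − min)/(max − min) per channel — the conventional way to put
cross-FA scans of different channels on a common [0, 1] axis.
Averaging aligns each profile on the reference channel's peak
(position 0), resamples to a shared grid (step = one sample spacing) on
the common support, and reports pointwise mean and SD. LOESS uses
tricube weights and local *quadratic* fits (degree 2, span 0.75 by
default); local quadratics follow curvature at peaks, which the
line-scan shapes require, and reproduce polynomial data exactly.

## Anisotropy

No single standard exists for "bundle anisotropy"; we use
structure-tensor coherency, the fibre-alignment score used for
cytoskeletal images (FibrilTool-style): gradients by central
differences, tensor products smoothed with a Gaussian (σ = 2 px
default), averaged over the ROI; score = (λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1].
`dominant_angle` is the orientation of the coherent *structures*
(perpendicular to the dominant gradient), in [−π/2, π/2) from the
column axis. A zero-gradient ROI returns score 0 with a `degenerate`
flag. Scores are comparable within this implementation only — not
numerically to any other tool's anisotropy scale.

## Dynamics

Kymographs: rows = space, columns = time; column t is the
width-averaged line profile of frame t.

Lifetimes are *minimum* (censoring-aware) lifetimes: one record per
contiguous presence run, `min_lifetime` = frames present × dt, censored
iff the run touches frame 0 or the last frame. Interruptions of ≤ 1
frame are bridged by default (blinking robustness; set `gap_frames=0`
for strict runs). Presence detection thresholds every frame at a single
level derived from frame 0 (per-frame thresholds flicker and inflate
turnover) and links objects as spatiotemporal connected components.
Formation rate = objects first appearing after frame 0, per minute of
observation (events·min⁻¹ per field of view; an areal normalisation is
deliberately not applied).

Tracking is greedy nearest-neighbour frame-to-frame assignment with a
hard displacement gate and no gap closing — adequate for sparse
nuclei-like detections at 5-min cadence, and documented as inadequate
for dense or fast objects. Migration metrics: speed = path/duration,
persistence = net/path ∈ [0, 1], forward progress = net/duration;
tracks observed < 8 h (default) are excluded, mirroring the standard
inclusion rule for overnight migration experiments.

## Function assays

Cell area: Otsu foreground → components → pixel count × pixel area,
with a 50 µm² debris floor. Clearance: cleared = pixels *strictly
below* the threshold (an explicit value standing in for a manual
threshold, or `"auto"` = Otsu), components < 5 µm² discarded as noise
holes, total divided by the cell count (given, or counted from a nuclei
channel).

## Statistics

All tests are two-sided. Mann-Whitney U switches to exact enumeration
when the smaller sample has ≤ 8 values and the pooled sample is
tie-free, else the normal approximation with tie and continuity
corrections. Kruskal-Wallis uses the tie-corrected H; Dunn's z is
computed on pooled ranks with the tie-corrected variance, and pairwise
p-values are Bonferroni-adjusted by default (Holm and unadjusted
available). Stars: **** p<0.0001, *** p<0.001, ** p<0.01, * p<0.05,
else ns (strict inequalities). `run_report` optionally bins each
group's values (random bins of 10) before testing, matching the
plotting convention; because it is genuinely ambiguous whether binned
points or raw objects should enter the tests, both modes are provided
and the binned/unbinned choice is always explicit in the output
manifest. The type-I error of the full binning+test pipeline at
α = 0.05 is verified by simulation (500 null datasets) in the
acceptance script.

## Problem sizes and numerical choices

Test and acceptance workloads use 400×400 px scenes with 12 objects for
segmentation recovery (10 seeds), 220×220 px scenes with four ≥500-px
objects for correlation calibration (20 seeds × 4 ρ values), 20-frame
time-lapses, 2000-step random walks (20 seeds) and 500 null simulations
for the α-calibration — sizes chosen so the whole suite completes in
well under a minute per stage on one CPU while leaving the measured
margins far from their contracts. Per-object Pearson r is computed in
float64 with the two-pass formula; LOESS solves weighted least squares
via `lstsq` on centred predictors for conditioning.

## Known limitations

- Otsu requires a genuinely bimodal histogram: on an image with *no*
  true structures it bisects the noise (~50% foreground) and the area
  filter then passes spurious mid-size speckles. The segmentation
  contract assumes structures are present; blank-field detection is out
  of scope.
- Correlation calibration is guaranteed for SNR ≥ 10; at lower SNR the
  mixing coefficient clips and high |ρ| targets become unreachable
  (the generator then delivers the maximum achievable correlation).
- The tracker performs no global optimisation and no gap closing;
  crossing or blinking objects will fragment.
- The generator does not model PSF blur, uneven illumination,
  photobleaching or camera gain; conclusions from passing tests apply
  to quantification logic, not to acquisition artefacts.
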