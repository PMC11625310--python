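# faquant

Quantification of focal-adhesion (FA) organisation, septin
colocalization and ECM-sensing function in fluorescence microscopy
images of adherent cells — with a seeded synthetic-scene generator that
provides complete ground truth, so every analysis stage is verifiable
without any real microscopy data.

## What it measures

Fibroblast focal adhesions appear as elongated, micron-scale paxillin
puncta at the ventral cell surface (TIRF imaging); septin-7 forms
filaments and bundles that associate differently with perinuclear
versus peripheral adhesions. The package implements the full
quantitative workflow around that biology:

- **Segmentation & morphometrics** — background subtraction (grayscale
  opening), median filter, Otsu threshold, connected components; objects
  kept in the single-FA band 0.20 µm² < A < 6 µm². Per object: area A,
  second-moment axes, roundness 4A/(π·major²), compartment class.
- **Object-based Pearson colocalization** — for each adhesion, the
  pixel-wise correlation r = Σ(aᵢ−ā)(bᵢ−b̄) / √(Σ(aᵢ−ā)²·Σ(bᵢ−b̄)²)
  between two channels over the object's own pixels, with the cell split
  into inner (perinuclear) and outer (peripheral) compartments by an
  edge-distance rule; values averaged in random bins of 10 adhesions for
  plotting/statistics.
- **Line-scan profiles** — bilinear cross-FA intensity scans, min-max
  normalized (i−min)/(max−min), peak-aligned on the reference channel,
  averaged, with local-quadratic LOESS smoothing.
- **Anisotropy** — structure-tensor coherency (λ₁−λ₂)/(λ₁+λ₂) of the
  ROI-averaged smoothed tensor, the standard fibre-alignment score.
- **Dynamics** — kymographs along a line; *minimum lifetimes*
  (frames present × Δt, censored when a run touches the movie's first or
  last frame) and formation rates from presence matrices; a greedy
  nearest-neighbour tracker; migration speed, persistence
  (net displacement / path length) and forward progress with the 8-hour
  minimum-observation inclusion filter.
- **Functional assays** — Otsu-based cell area, and fibronectin
  clearance per cell (sub-threshold cleared area ÷ cell count).
- **Statistics** — Mann-Whitney U (exact by enumeration for small
  tie-free samples), Kruskal-Wallis + Dunn's post hoc (Bonferroni by
  default), significance stars (****, ***, **, * at p < 0.0001 / 0.001 /
  0.01 / 0.05).
- **Synthetic scenes** (`faquant.synthetic`) — seeded two-channel FA
  scenes with *known* per-object correlation ρ (calibrated so the
  expected measured r of the noisy channels equals ρ), time-lapses with
  known lifetimes, filament fields, clearance scenes with exactly known
  hole areas, and migration tracks — each with full ground truth.

## Worked example

```python
from faquant import SceneParams, generate_fa_scene, run_report
from faquant.pipeline import analyze_scene

scene = generate_fa_scene(SceneParams(n_objects_inner=12, n_objects_outer=12,
                                      rho_inner=0.3, rho_outer=0.8, seed=42))
df = analyze_scene(scene.channels, "paxillin", cell_mask=scene.cell_mask)
print(df.groupby("region")["pearson_paxillin_septin"].median().round(3))
print(run_report(df, "region", "pearson_paxillin_septin").round(4).to_string(index=False))
```

prints

```
region
inner    0.300
outer    0.813
Name: pearson_paxillin_septin, dtype: float64
    comparison                      test  n_a  n_b  median_a  median_b  statistic  p_value stars
inner vs outer mann-whitney (asymptotic)   12   12    0.2996    0.8128        0.0      0.0  ****
```

The generator placed 24 adhesions with true correlation 0.3 (inner) and
0.8 (outer); the pipeline segments them from the noisy paxillin channel,
classifies each by compartment, recovers the per-object correlations
(medians 0.30 and 0.81), and the Mann-Whitney comparison of the two
compartments is significant at the **** level.

The same stages are available from the shell: `synth fa-scene|timelapse|
clearance|tracks` to generate data, `faq coloc` / `faq report` to
analyse it.

## Layout

- `src/faquant/synthetic.py` — ground-truth scene generators
- `src/faquant/imageops.py` — shared raster operations
- `src/faquant/adhesions.py` — segmentation, morphometrics, per-object r
- `src/faquant/profiles.py` — line scans, normalization, LOESS
- `src/faquant/texture.py` — structure-tensor anisotropy
- `src/faquant/dynamics.py` — kymographs, lifetimes, tracking, migration
- `src/faquant/assays.py` — cell area, fibronectin clearance
- `src/faquant/stats.py` — nonparametric tests and reporting
- `docs/methods.md` — models, conventions, parameter rationale, limits
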