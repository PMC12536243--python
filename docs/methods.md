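# Methods

This note documents the models, parameter choices and numerical conventions
behind `gutseg`, the reasoning where the design was genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## The three-step segmentation model

The pipeline assumes a calibrated brightfield RGB scan of a full-wall
small-intestinal section and produces nested compartment masks with areas
in µm².

**Step 1 — tissue detection.** The mean of the three colour channels is
smoothed with a Gaussian (σ = 2.0 px) at the working resolution of
7.03 µm/px and thresholded at 205: pixels *strictly below* the cutoff are
tissue. The threshold value sits between stained tissue (mean RGB roughly
110–200 for the stain intensities considered here) and illuminated
background (≥ 240), so the exact boundary convention matters only for the
measure-zero case of a pixel landing exactly on 205; we assign it to
background. Thresholding is intrinsically blind to *what* is stained —
stained luminal content is accepted as tissue and unstained tissue
(dilated lymphatics, edema) is rejected — which is the dominant,
non-trainable error source of this step.

**Object creation.** Binary classifications become measurable objects by
(1) removing 8-connected components whose area is below the minimum object
size and (2) filling 4-connected interior holes (background components not
touching the raster border) whose area is below the minimum hole size.
Components or holes exactly at a minimum survive. Steps 1–2 use
10,000 µm² / 100,000 µm²; step 3 uses 1,000 µm² for both. The complementary
8/4 connectivity pairing avoids the topological paradox of a diagonal
"channel" simultaneously connecting an object and splitting a hole. The
cleaned raster is the fixed point of the operation (cleaning is
idempotent), and in the hierarchical pipeline it is intersected with the
parent-stage mask after cleaning, so hole filling can never leak a child
compartment outside its parent. Outlines are traced by marching squares at
the 0.5 level and areas computed by the shoelace formula; polygon areas
agree with pixel-count areas to within a one-pixel boundary band (marching
squares cuts half-pixel corners), and all reported areas and IoU values
are computed on the rasters, not the polygons, to avoid floating-point
geometry artefacts on highly irregular villous outlines.

**Steps 2–3 — trainable pixel classification.** Both stages are random
forests (100 trees, √p features per split, unlimited depth, no class
weighting, fixed seed — all recorded in the model manifest) trained on the
features at brush-annotated pixels only; there is no background sampling,
mirroring brush-tool supervision. Stage 2 separates mucosa from
submucosa/muscularis at 7.03 µm/px with Gaussian, Laplacian-of-Gaussian,
weighted-deviation and Hessian-determinant features at σ ∈ {1.0, 2.0};
stage 3 separates epithelium from lamina propria at 3.51 µm/px adding
gradient magnitude and structure-tensor coherence at σ = 1.0. Scales are
interpreted as the Gaussian σ in working-resolution pixels. Each stage is
applied only inside the objects of the previous stage; pixels outside the
restriction are "unclassified" and ties in forest votes break toward the
first declared class. Channels are R, G, B and the hematoxylin
concentration from a per-image stain fit (below).

The two printed working resolutions are treated as an exact 2× pair:
images are generated at 3.51 µm/px and the coarse stages use 2× block-mean
downsampling, with resampling ratios within 0.5 % of an integer snapped to
that integer. This avoids the resampling ambiguity that the literal ratio
7.03/3.51 = 2.0028 would introduce, at the cost of a ≤ 0.3 % calibration
inconsistency absorbed into the stated µm/px values.

## Filter bank numerics

All filters are separable convolutions with sampled Gaussian kernels
(truncation 4σ, reflect padding everywhere — reflect avoids the edge
darkening that constant padding would feed into the threshold and texture
features). Two deliberate numerical choices:

- The order-2 derivative kernel's truncation residue is folded into its
  centre tap so the kernel has exactly zero total weight: constant images
  produce exactly zero Laplacian-of-Gaussian and Hessian responses rather
  than an O(10⁻⁴) truncation bias. The order-1 kernel is antisymmetric and
  zero-sum by construction.
- "Weighted deviation" is implemented as the Gaussian-weighted local
  standard deviation `sqrt(max(0, G_σ∗I² − (G_σ∗I)²))` — the plain reading
  of the name. The variance is floored to zero below the floating-point
  cancellation level (10⁻¹² relative to the local second moment), so
  constants respond exactly 0 instead of `sqrt(eps)`.
- Structure-tensor coherence is `(λ₁−λ₂)/(λ₁+λ₂+ε)` with ε = 10⁻¹²,
  derivative and integration scale both σ, and the value defined as 0
  where the tensor trace is at noise level (both eigenvalues ≈ 0).

Every filter is verified against an independent brute-force oracle: dense
2-D convolution with explicitly constructed kernels, and a per-pixel
eigendecomposition for coherence.

## Stain model

RGB is converted to optical density per Beer–Lambert,
`OD = −log₁₀(max(I,1)/I₀)`, with intensities clamped at 1 so OD stays
finite; the white point is fixed at (255, 255, 255) because the generator
guarantees near-white background (an estimation mode would be the natural
extension for real scanners). Stain vectors are refit per image in the
Macenko style: tissue pixels (mean RGB ≤ 205, total OD > 0.05) are
projected onto the top-2 right-singular plane of their OD cloud and the
1st/99th percentiles of the in-plane angle give the two stain directions,
clipped to the non-negative orthant and unit-normalised. The vector with
the larger red-channel absorbance is hematoxylin (hematoxylin absorbs red
and green strongly and transmits blue; eosin absorbs green almost
exclusively). With fewer than 200 usable tissue pixels the published
default H&E vectors are used and the model flags the fallback.
Deconvolution is the per-pixel least-squares projection onto the two
vectors with negative concentrations clipped to zero; models whose vectors
are within 1° of collinear are refused. Only the hematoxylin channel feeds
the classifiers; eosin is computed for diagnostics.

A note on scope: per-image refitting calibrates the *deconvolution basis*;
it does not alter the RGB values the classifiers see. Whether upstream
tools rescale pixel values during "stain normalization" is ambiguous; the
basis-refit interpretation is the conservative one and is what is
implemented.

## The synthetic benchmark

The generator emulates the statistics the pipeline consumes — layer
topology, colour separation, texture scale, calibration — and nothing
more. A section (default 448×448 px at 3.51 µm/px ≈ 1.6×1.6 mm) is a
horizontal stack: muscularis (245 µm, oriented fibre banding), submucosa
(315 µm, smooth pale texture), a crypt band (245 µm of speckled lamina
propria), and capsule-shaped villi (default 380 µm long, 120 µm wide) with
an epithelial rim defined as all mucosa within 32 µm of the lumen.
Colours are produced physically: each class has hematoxylin/eosin
concentrations mixed through per-image jittered stain vectors (σ = 0.02
per component) and Beer–Lambert exponentiation, plus multiplicative
texture fields and per-pixel Gaussian RGB noise (σ = 4). Background
renders at mean RGB ≈ 252, all tissue classes below 200, so the printed
205 threshold is meaningful by construction.

Age groups map to two morphological axes, both monotone in age:
vacuolation fraction (0.50, 0.30, 0.12, 0.04, 0.00 for 4, 14, 25, 49, 67
days) and inter-villus gap (18–46 µm). Vacuolated "fetal-type" epithelium
is selected as the distal row-quantile of epithelial pixels matching the
requested fraction and rendered pale (ground truth remains epithelium) —
the synthetic counterpart of the main age-dependent difficulty in real
neonatal sections. Goblet cells are pale 2-px discs seeded on the
epithelial surface at 8 cells/mm. Cohorts additionally jitter villus
length (±20 %) and width (±10 %) per sample so that areas genuinely vary
between animals and area correlations are informative. Since no
quantitative description of debris or goblet appearance exists to fit
against, their concentrations and sizes are stated constants chosen once
to be visually plausible and spectrally distinct.

Artifacts reproduce the documented error modes with exact ground truth:

- **Luminal debris** — 2–4 stained elliptical blobs inside the lumen,
  labelled `lumen_content` (not tissue). Step 1 accepts them as tissue, so
  the measured area inflates (mean step-1 RD ≈ +2 to +3 % over the
  baseline +1–2 % boundary dilation).
- **Edema vessels** — one unstained ellipse (~125,000 µm², deliberately
  above the 100,000 µm² hole minimum) in the submucosa, labelled
  `submucosa_muscularis` because an empty vessel is still tissue. Step 1
  thresholds it as background and the hole survives filling, deflating the
  area (mean RD ≈ −6 %).
- **Crypt abscesses** — debris-filled discs carved from the lamina
  propria, labelled `lumen_content`, matching the annotation convention
  that treats their classification as lamina propria as an error.

Brush annotations are sampled as disc-swept random walks confined to the
class region eroded by the brush radius (25 µm for stage 2, 7 µm for
stage 3), so every stroke pixel carries its class label with certainty —
an idealisation of a careful annotator. Training-set "designs" ship as
small-cohort presets (15 sections / 236 annotations for stage 2; 8/172
ad hoc and 10/285 age-balanced for stage 3, the age-balanced composition
taken as two per group) with the budget spread round-robin over
(sample, class) slots.

Everything is deterministic given one master seed; cohort sample *i* uses
seed `(master·100000 + i) mod 2³¹`.

### What the benchmark does and does not show

Passing the synthetic suite shows the machinery is correct and that the
documented error modes have the predicted directions and rough magnitudes.
It does not show performance on real slides: the generator has no
scanner optics, focus artifacts, folds, pen marks, Peyer's patches,
autolysis, or the full histological variability of real mucosa, and its
class palettes are far better separated than worst-case faded stains. The
held-out quality floors (mean IoU ≥ 0.90 tissue / 0.80 mucosa / 0.75
epithelium on 20 sections with 10 training sections) should be read as
regression guards on the pipeline, not as claims about tissue.

## Evaluation conventions

- RD is signed; summary tables report the signed mean and SD per
  (step, design, age group). Agreement categories fold to |RD| with
  half-open intervals and boundaries assigned upward: [0,5) very good,
  [5,10) good, [10,20) fair, [20,∞) poor.
- IoU is computed on rasters at each step's working resolution; ground
  truth is majority-downsampled (block mean ≥ 0.5) for the coarse steps.
  An empty union is an error, not a value. Interpretation bands use strict
  inequalities: >0.50 acceptable, >0.75 good, >0.90 near-perfect.
- Pearson correlations are labelled ≥0.90 very strong, 0.70–0.90 strong,
  0.50–0.70 moderate, 0.30–0.50 weak; groups with n < 3 or zero variance
  report "not computable" while all other statistics are still emitted.
- "All" rows pool records across groups (pooled mean, not the mean of
  group means).
- Step 1 is scored on the tissue compartment, step 2 on mucosa, step 3 on
  epithelium. Synthetic sections are evaluated whole-frame; the manual
  selection of a measurement segment along the lamina muscularis on real
  slides has no algorithmic definition and is out of scope.

## Problem sizes

The shipped defaults — 448² px sections, 30-section cohorts, 10 training /
20 validation, ten seeds per directional experiment — were chosen so a
full benchmark run completes in minutes on a single CPU while keeping
every mean over ≥ 10 independent draws. All sizes are ordinary function
arguments and scale up without code changes.

## Known limitations

- The forest hyperparameters are sensible defaults, not tuned; "default
  random trees" is under-specified upstream and the manifest records what
  was actually used.
- Whether stage 2 should see the full image or only step-1 objects is
  ambiguous in interactive workflows; the hierarchy is enforced here
  (containment is exact by construction), which also means step-1 errors
  propagate downward — as they do in the interactive original.
- Thin-rim compartments (epithelium ~9 px wide at working resolution) put
  a hard ceiling on IoU from single-pixel boundary uncertainty alone:
  a systematic one-pixel error on both edges of a 9-px rim caps IoU near
  0.64. Observed values (~0.8) sit between that and the perfect-boundary
  limit.
- The generator's single-observer, noise-free ground truth cannot probe
  inter-observer variability; agreement statistics measure machinery, not
  annotation quality.
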