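# Methods

`siliquant` turns per-instance segmentation masks of siliques (the
elongated seed pods of *Arabidopsis* and other Brassicaceae) into
QC-filtered morphometric traits, sample-level aggregate phenotypes,
treatment statistics, and detection/segmentation evaluation reports.
This note records the models, conventions and numerical choices behind
each stage, and what the synthetic test surface does and does not show
about real data.

## Instance model and I/O

An instance is a full-frame binary raster plus a COCO-style bounding box
`(x, y, w, h)` (0-based pixels, origin top-left), a confidence score
(1.0 for annotations) and an image id. Masks are **amodal**: overlapping
instances may share pixels, so each instance keeps its own raster —
a single label image cannot express overlap. Two dialects are read and
written: COCO instance JSON (polygon, list-RLE and compressed-string-RLE
segmentations) and a mask-folder layout (`<image_id>/<instance_id>.png`
plus a versioned `metadata.json` sidecar; the sidecar schema is this
package's own reconstruction of a per-instance-mask folder convention
and is versioned via `format_version`). A stored bbox that fails to
enclose the mask's foreground is recomputed to the tight pixel bounds.
A manifest row with a blank dpi defaults to 300 — the common flatbed
scan resolution for this material — with a logged warning.

## Mask quality control

A mask is accepted only if

1. it has exactly one 8-connected foreground component;
2. its Zhang–Suen skeleton, after spur pruning, is one open curve
   (exactly 2 endpoints, 0 branch points).

Spur pruning deletes every terminal branch of at most `max_spur_px`
pixels (default 5, counted excluding the branch point), shortest first,
recomputing the topology after each deletion until stable; the mask set
is re-thinned after each deletion because T-junction pixel clusters can
otherwise leave a one-pixel stub whose degree never drops below 3.
A branch longer than the threshold that survives pruning marks the mask
as `residual_spur` — typically two fused siliques. Masks with holes
(skeleton cycles, no endpoints) or that thin to a single pixel are
`degenerate_skeleton`. 8-connectivity is used throughout: it is the
standard choice for thin diagonal structures and the neighbourhood the
thinning algorithm itself operates on.

The 5-px boundary admits two readings — prune small spurs, or reject
any spurred mask outright. This package prunes at ≤ 5 px and rejects
only persisting longer branches, so small thinning artefacts are
harmless and genuinely aberrant masks are fatal. Repairing bad masks
(splitting fusions, filling holes) is out of scope.

## Traits

With `s = 25.4 / dpi` mm per pixel:

* **SA** (mm²) — foreground pixel count × s².
* **SL** (mm) — geodesic step-sum along the ordered skeletal path
  (1 px orthogonal, √2 diagonal) × s. A chord would misreport curved
  pods; the step-sum follows the spine.
* **SD** (mm) — 2 × max Euclidean distance transform (EDT) over
  skeleton pixels × s. The EDT is the distance to the nearest
  *background pixel centre*, with no half-pixel correction — the common
  library semantics; the radius estimate therefore carries a systematic
  excess between 0 and 1 px (exactly +1 px for an axis-aligned tube of
  integer radius), absorbed by the stated tolerances.
* **SV** (mm³) — one disk per skeleton pixel, radius EDT(pixel),
  height one voxel: SV = Σ π r² × s³. An alternative
  `disk_height="step"` weights each disk by the local step length
  (trapezoid rule along the spine), removing the orientation dependence
  of the literal unit-height stack; the unit-height reading is the
  default.

Known, documented biases (measured on the synthetic capsules below):

* SL has no tip compensation; thinning may inset each tip by up to one
  radius (underestimate ≤ 2r). In the opposite direction the chain-code
  step-sum overestimates digital line length by up to ~8% of L at
  orientations near 22.5° (the classic metrication error), plus ~1%
  skeleton wiggle. On random orientations the total SL error can reach
  ~9.5% of L, which for long thin capsules exceeds 2r: a tolerance of
  2r px is **not attainable** for this estimator on such shapes, and
  the recovery test that asserts it documents the genuine failure.
* SV combines the EDT radius excess (inflates, up to (1 + 1/r)²) with
  the unit disk height on diagonal spines (deflates, ×0.71 at 45°).
  The per-capsule ratio estimate/truth was measured once against the
  closed-form integral ∫ π r(t)² ds on the seeded 200-capsule suite and
  frozen as the regression band **[0.75, 1.10]**; across other random
  draws the worst case approaches ±25%. The band is a regression
  guard for this estimator's known discretisation biases, not a claim
  of unbiasedness.
* SA and SD recover to within ±2% and ≤ 1.6 px respectively on the
  same suite (asserted at 3% and 2 px).

## Synthetic capsules, scenes, aberrations, populations

A synthetic silique is a capsule: a smooth centerline (spline through
control points) with a radius profile r(t) ≥ 1 px, rasterised by the
rule *pixel foreground iff its centre lies within r of the centerline*.
Ground truths are computed on the continuous shape by trapezoid
quadrature at 0.25 px spacing: length = arclength, area = ∫ 2r ds plus
semicircular caps, volume = ∫ π r² ds (no caps — the disk-stack target
quantity), max radius from the profile. Defaults for random capsules
(length 60–160 px, radius 4–8 px, sagitta ≤ 15% of length, taper ≤ 30%,
uniform orientation) mimic scanned rosette material at 300 dpi, where
pods are roughly 5–14 mm long and 5–10 px across. Generation is
deterministic given the spec; scenes, perturbed "predictions"
(identity/dilate/erode/shift with assigned confidences) and phenotype
populations all flow from single integer seeds.

Aberrant masks are constructed to trigger specific QC codes: a disjoint
blob (`multi_component`), a 1-px perpendicular protrusion calibrated so
the *measured* skeleton branch equals the requested spur length
(`spurred`), and two crossed capsules (`fused_pair`).

Phenotype populations follow the additive model
`value = μ + line_effect + treatment_effect·1[group] + ε` with
`line_effect ~ N(0, σ²_line)` and `ε ~ N(0, σ²_resid)`, two treatments
(isolation vs group growth) fully crossed with lines. Broad-sense
heritability of the generated values within a treatment is
σ²_line / (σ²_line + σ²_resid) by construction.

What the synthetic surface does **not** emulate: pedicels, branches and
background texture; occlusion-driven segmentation errors; non-Gaussian
phenotype tails; batch effects. Passing tests therefore demonstrate the
correctness of the computations, not field performance of any detector.

## Aggregation and statistics

Per sample and trait: mean, percentiles {5, 25, 50, 75, 95} by linear
interpolation between order statistics (the most common convention; the
choice moves P95 by less than one inter-silique gap), RSD = sd(n−1) /
mean, and accepted/rejected counts. A sample with no accepted instance
is missing, never zero. The P95 phenotype is the usual choice for
mapping: it tracks the best pod a plant produced and, empirically, has
the strongest line signal; RSD tracks within-sample uniformity.

Genotype-level exclusion removes *all* samples of a flagged line across
batches and treatments (an aberrant plant disqualifies its genotype's
replicates), honouring an external flag list; the biological judgement
behind a flag is not modelled.

The treatment contrast is a classical paired t-test on per-genotype
means (replicates averaged within each treatment); genotype is the only
unit present in both treatments, hence the pairing key. Genotypes
missing a treatment are dropped and counted. Broad-sense heritability
is the one-way ANOVA repeatability per treatment:
H² = σ̂²_line / (σ̂²_line + σ̂²_resid) with method-of-moments components
and the standard unbalanced-design correction
n₀ = (N − Σnᵢ²/N)/(k − 1), clipped to [0, 1]. Batch is exported as a
covariate rather than modelled inside the estimator.

Calibration, verified by simulation: under the null the paired test
rejects at 5% ± 2% (1,000 populations), and heritability recovery over
true H² ∈ {0.1 … 0.9} at 300 lines × 3 replicates has mean absolute
error < 0.1 (measured ≈ 0.02).

## Detection / segmentation evaluation

Greedy score-ordered one-to-one matching per image: each prediction, in
descending confidence (ties by stable input order), claims the
highest-IoU unmatched ground truth with IoU ≥ threshold. AP is the mean
of interpolated precision at 101 equally spaced recall points
(precision at recall r = max precision at recall ≥ r); an
`all_points` interpolation switch is provided for sensitivity. AR is
TP/(TP+FN) at the full detection budget. Headline metrics: AP@0.5,
AP@0.75, and AP/AR averaged over thresholds 0.5:0.05:0.95, reported as
percentages, separately for boxes (detection) and pixel masks
(segmentation). No per-image detection cap and no object-area ranges
are applied. The greedy matcher is verified against an exhaustive
independent matcher on random small scenes at every threshold.

## Study-design arithmetic

Deterministic bookkeeping: `split_dataset` partitions image ids with a
floor-sized training set (55 images at 80% → exactly 44/11; the floor
rule only matters for non-integral products, and sizes never depend on
the seed); `training_iteration_count` = epochs × ceil(n_train /
effective batch) (36 × ceil(44/2) = 792; ceil only matters for a
partial final batch); `genetic_map_summary` totals per-chromosome
marker counts (274+210+248+228+290 = 1,250 across 5 chromosomes).

## Problem sizes in the default test run

The shipped suite uses 200 capsules for the recovery sweep, 100 random
scenes × 10 thresholds for matcher equivalence, 1,000 simulated
populations (40 lines × 2 replicates) for type-I calibration, and a
9-point heritability grid at 300 × 3 — sizes at which every Monte-Carlo
band in this note is comfortably resolved.
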