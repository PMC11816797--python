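# siliquant

Instance-mask morphometrics for silique phenotyping.

Siliques — the elongated seed pods of *Arabidopsis thaliana* and other
Brassicaceae — are a direct readout of reproductive output, and modern
instance-segmentation networks can delineate every pod on a scanned
stem. What remains between a folder of predicted masks and a phenotype
table ready for QTL mapping is exactly the part that is easy to get
subtly wrong: quality-controlling each mask, measuring it in metric
units, aggregating thousands of pods per pot into line-level
phenotypes, and scoring the detector itself. `siliquant` is that part,
for geneticists and plant phenotyping groups working with per-instance
(amodal) silique masks.

## What it computes

Per accepted mask, with `s = 25.4/dpi` mm per pixel:

| Trait | Definition |
|---|---|
| SA (mm²) | foreground pixel count × s² |
| SL (mm)  | step-sum along the pruned Zhang–Suen skeleton (1 px orthogonal, √2 diagonal) × s |
| SD (mm)  | 2 × max Euclidean distance transform over skeleton pixels × s |
| SV (mm³) | Σ over skeleton pixels of π·EDT² (1-voxel-high disks) × s³ |

A mask is accepted only if it is a single 8-connected component whose
skeleton, after pruning spurs of ≤ 5 px, is one clean open curve;
rejections carry reason codes (`multi_component`, `residual_spur`,
`empty_mask`, `degenerate_skeleton`). Per sample, each trait is
summarised by mean, percentiles {5, 25, 50, 75, 95} and RSD (sd/mean);
line-level utilities provide a paired treatment t-test (per-genotype
means), one-way ANOVA broad-sense heritability H² =
σ²_line/(σ²_line+σ²_resid), genotype-level exclusion bookkeeping, and a
mapping-ready phenotype/covariate CSV export. A separate evaluation
module scores predictions against ground truth with greedy
score-ordered IoU matching and reports AP@0.5, AP@0.75 and AP/AR over
IoU 0.5:0.05:0.95 for boxes and masks. A synthetic generator produces
capsule masks with closed-form trait truths, multi-instance scenes, QC
provocations and line×treatment phenotype populations, so the whole
pipeline is testable with no image data. See `docs/methods.md` for
conventions and known biases.

## Worked example

```
$ siliquant simulate --n 12 --n-aberrant 2 --seed 1 --out demo/scene
wrote 14 ground-truth and 12 predicted instances to demo/scene

$ siliquant traits --instances demo/scene/ground_truth.json --out demo/traits
INFO siliquant: rejected instance=aberrant-multi_component-100 image=synthetic reason=multi_component
INFO siliquant: rejected instance=aberrant-spurred-101 image=synthetic reason=residual_spur
INFO siliquant: QC: 12 accepted, 2 rejected (rejection_rate=0.1429)
wrote 14 instance rows (2 rejected) to demo/traits
```

The scene held 12 clean synthetic pods plus two deliberately aberrant
masks; QC rejected exactly those two, with their reasons logged and
kept as rows in the trait table. The first accepted rows:

```
instance_id,image_id,sample_id,qc_status,qc_reason,SA_mm2,SL_mm,SD_mm,SV_mm3,dpi
scene-0-gt-0,scene-0,scene-0,accepted,,8.215037,7.542383,1.135923,5.523772,300.000000
scene-0-gt-1,scene-0,scene-0,accepted,,5.856619,6.890578,0.911888,3.483580,300.000000
```

— a 7.5 mm-long pod, 1.14 mm across at its widest, 8.2 mm² projected
area, 5.5 mm³ of disk-stack volume at 300 dpi. The sample aggregate for
SL reads mean 7.55 mm, P95 9.38 mm, RSD 0.20 over 12 accepted pods.
Scoring the simulated predictions (here mildly imperfect because the
two aberrant ground-truth masks have no matching prediction):

```
$ siliquant evaluate --ground-truth demo/scene/ground_truth.json \
      --predictions demo/scene/predictions.json --out demo/eval
      Metric  AP_50_95     AP_50     AP_75  AR_50_95
   Detection 85.148515 85.148515 85.148515 85.714286
Segmentation 85.148515 85.148515 85.148515 85.714286
```

The same operations are available as library functions
(`siliquant.extract_traits`, `siliquant.aggregate_table`,
`siliquant.evaluate`, …) for notebook use.

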