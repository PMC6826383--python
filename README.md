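# budscreen

Morphometric screening of immunostained epithelial particles for
metastasis prognosis.

## The problem

In breast-tumor sections stained with a pan-cytokeratin antibody
(epithelial cells dark on a light background), malignant epithelium
appears as irregular clusters of widely varying size and shape — and, in
between them, as scattered individual cells in the stroma. Which of these
morphologies carries prognostic information for distant metastasis is not
obvious a priori. `budscreen` implements a hypothesis-free discovery
procedure for that question: binarize each image, outline and measure
every stained particle, define particle *subsets* with circularity and
size filters, and evaluate every subset's features against time-to-
metastasis outcome.

For each particle, size and shape descriptors are computed the way the
field's particle analyzers define them:

* circularity `4·π·area / perimeter²` (1 for a circle, → 0 when
  elongated, capped at 1),
* solidity `area / convex-hull area`,
* maximum Feret (caliper) diameter, perimeter and pixel area.

The default screening grid crosses 4 binarization thresholds (automatic
intermeans, 220, 240, 250) × 5 circularity minima (0, 0.2, 0.4, 0.6,
0.8) × 4 size minima (10, 20, 50, 100 px) = **80 particle subsets**, each
scored on 5 features (count, total area, average size, mean circularity,
mean solidity). Each record gets

* a Mann–Whitney AUC on the continuous per-patient feature (averaged over
  the patient's images), with Harrell-style bootstrap optimism
  correction, and
* a Cox proportional-hazards fit (Breslow ties) on the X-tile-style
  optimal-cutpoint dichotomization (maximally selected log-rank
  statistic),

and records are ranked by `|corrected AUC − 0.5|`. A synthetic-data
module generates tumor-like images and full patient cohorts with a known
planted signal, so the whole pipeline is testable without any external
data.

Audience: image-analysis and biostatistics researchers who want a tested,
scriptable re-implementation of this screening procedure, or a synthetic
testbed for morphometric biomarker discovery methods.

## Worked example

Simulate a small cohort whose metastasis risk is driven by the density of
scattered single cells (generating AUC 0.82), then screen all 80 subsets:

```python
from budscreen import CohortSimSpec, SubsetScreen, generate_cohort

spec = CohortSimSpec(n_patients=60, n_events=14, images_per_patient=3)
cohort = generate_cohort(spec, seed=3)

model = SubsetScreen(cohort.table, cohort.images, bootstrap_B=500)
results = model.fit(seed=3)

top = results.top
print(top.spec.label, top.feature)
print(results.summary(5))
```

Output (this exact run):

```
optimal subset : bin=250|circ=0.8-1|size=20-inf
feature        : count
AUC            : 0.77 (95% CI 0.61-0.93, p=2.3e-03)
corrected AUC  : 0.77
cutpoint       : 8.17 particles/image
hazard ratio   : 8.5 (95% CI 2.3-31.8, p=1.4e-03)

binarization  circularity_min  size_min_px     feature   auc  corrected_auc    hr
         250              0.8           20       count 0.770          0.774 8.546
         220              0.8           20       count 0.770          0.772 8.546
        auto              0.8           20       count 0.770          0.771 8.546
         240              0.8           20       count 0.770          0.770 8.546
         250              0.4           20 circularity 0.769          0.769   NaN
```

The screen identifies the planted subset: small (≥ 20 px ≈ 7 µm
equivalent diameter at 1.4 µm/px), highly circular (circularity ≥ 0.8)
particles — the scattered single cells — with their *count* as the
leading feature. The hazard ratio of 8.5 says patients above the optimal
cutpoint (here ~8 single cells per image) had an ~8-fold higher
metastasis rate than those below it; the corrected AUC is the
discrimination estimate after subtracting bootstrap optimism. The NaN
hazard ratio in the fifth row is a deliberately reported failure: that
record's dichotomization separated the groups perfectly, so the Cox
likelihood is monotone and no finite estimate exists. At this small n the
estimates are noisy (note the wide CIs); the test suite runs the same
experiment at 102 patients × 5 images with 20 events, 25 times.

The same screen runs from the shell on a directory of PNG/TIFF images and
a cohort CSV:

```bash
budscreen simulate --out synthetic/ --seed 7
budscreen run --cohort synthetic/cohort.csv --out results/
budscreen profile --cohort synthetic/cohort.csv --windows 1,10,20,60,80
```

`profile` reports the count feature's AUC per particle-size window; on
cohorts with the planted signal it peaks in the 20–60 px (single-cell)
window.

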