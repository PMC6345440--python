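# deepstroma

Prognostic tissue decomposition of colorectal-cancer H&E histology.

For virtually every colorectal cancer (CRC) patient a hematoxylin–eosin
(H&E) slide exists, and the *stromal* compartment visible in it —
desmoplastic stroma, lymphocytes, debris, muscle, adipose tissue —
carries prognostic information that routine reporting ignores. This
package implements, as a tested and reusable pipeline, a biomarker that
mines it:

1. **Stain normalization** — Macenko optical-density/SVD normalization
   of RGB images to a reference H&E profile.
2. **Tissue classification** — a nine-class classifier (ADI, BACK, DEB,
   LYM, MUC, MUS, NORM, STR, TUM) emitting a softmax activation vector
   per 224×224 patch.
3. **Tile decomposition** — sliding-window classification of
   1,500×1,500 px multitissue regions; region vectors are tile-mean
   activations, patient vectors are the elementwise max over regions.
4. **Deep stroma score** — per class c, a univariable Cox fit gives a
   hazard ratio HR_c, and ROC analysis against the survival event gives
   a Youden-optimal activation cutoff τ_c; classes with HR_c > 1 are
   combined into

       S = Σ_{c : HR_c > 1} HR_c · 1[a_c > τ_c],

   dichotomized at the training-cohort median (frozen for validation
   cohorts) and assessed in multivariable Cox models with UICC stage,
   sex, and age in decades. The published-2019 preset ships the printed
   HR weights, cutoffs, and median (8.347) as a frozen `ScoreModel`.

A first-class **synthetic-data module** generates separable procedural
tissue textures, composite regions with ground-truth masks, and
cohorts with exponential proportional-hazards survival, so the whole
pipeline runs and is tested without any external data. See
`docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
import json
from deepstroma import demo_config, run_pipeline

run_pipeline(demo_config("demo_out", seed=7))
report = json.load(open("demo_out/survival_report.json"))
```

The demo synthesizes a 120-patient cohort with planted log-hazard
effects on debris (log 6) and muscle (log 4), builds the score, and
runs the survival analyses. With seed 7 it prints:

```
uni HRs   ADI 1.386  BACK 0.616  DEB 9.101  LYM 2.147  MUC 1.069
          MUS 2.508  NORM 0.356  STR 0.536  TUM 0.747
selected  ['ADI', 'DEB', 'LYM', 'MUC', 'MUS']   median 1.766
group HR  2.34  [1.49, 3.66]  p = 2.1e-04
```

Reading this: the planted risk classes DEB and MUS come back with the
largest univariable hazard ratios; the HR > 1 rule selects them (plus
three weakly positive classes — expected sampling noise at n = 120);
and the median-split high-score group carries a significantly elevated
multivariable hazard (CI excludes 1) after adjusting for stage, sex,
and age.

The scikit-learn estimator surface composes with sklearn tooling:

```python
from deepstroma import CohortConfig, DeepStromaScorer, generate_cohort
import numpy as np

cohort = generate_cohort(CohortConfig(n_patients=500, seed=1,
                                      beta={"DEB": np.log(6)}))
scorer = DeepStromaScorer(endpoint="OS").fit(cohort)
scores = scorer.transform(cohort)      # deep stroma score per patient
labels = scorer.predict(cohort)        # high/low at the frozen median
```

A CLI mirrors the stages: `deepstroma generate-data | stain-normalize |
train-classifier | evaluate | decompose | build-score | apply-score |
run`.

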