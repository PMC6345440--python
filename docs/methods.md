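# Methods

`deepstroma` implements a prognostic-biomarker pipeline for colorectal
cancer (CRC) built on routine hematoxylin–eosin (H&E) histology: color
normalization, nine-class tissue-texture classification, sliding-window
decomposition of multitissue images, and a hazard-ratio–weighted
composite risk score ("deep stroma score") evaluated with proportional-
hazards survival models. A procedural synthetic-data module generates
every input the pipeline needs, so all stages are testable end to end
without clinical data. This note records the models, the defaults, and
the design choices that were genuinely open.

## Tissue taxonomy

Nine classes, fixed alphabetical order used for every vector and matrix:
ADI (adipose), BACK (background), DEB (debris/necrosis), LYM
(lymphocytes), MUC (mucus), MUS (smooth muscle), NORM (normal colon
mucosa), STR (cancer-associated stroma), TUM (adenocarcinoma
epithelium).

## Stain normalization (Macenko)

Stain mixing is linear in optical density, OD = −log10(max(I, 1)/I0)
with I0 = 255 and the intensity clamped to 1 before the log (log base
and guards are our choices; the method itself leaves them open).
Estimation: pixels with max-channel OD > β (default 0.15) are projected
onto the plane of the top two singular vectors of the OD cloud; the
α-th and (100−α)-th percentile angles (α = 1) define the hematoxylin
and eosin directions, with hematoxylin identified as the column with
the larger blue-channel OD component. Concentrations are obtained by
exact two-column nonnegative least squares (vectorized closed form),
which stays stable when a patch is dominated by a single stain and the
two estimated directions become nearly collinear — the `lstsq`-then-
clip shortcut visibly corrupts reconstructions there. The per-stain
99th-percentile concentration is stored; normalization rescales
concentrations by target/source maxima and reconstructs through the
target matrix.

Two numerical choices worth recording:

* **Exposure offset.** Uniformly dimming an image by a factor c shifts
  every OD vector by −log10(c)·(1,1,1), so the stain plane becomes
  affine. We fit the affine plane (centered PCA) and solve for the
  isotropic offset that restores it through the origin; for undimmed
  images the estimate is ≈ 0 and we only correct offsets |δ| > 0.04
  (≈ 10% intensity), because smaller fitted offsets arise spuriously
  from texture curvature and correcting them destabilizes repeated
  normalization.
* **Degeneracy guards.** Fewer than 100 stained pixels → "insufficient
  stained pixels"; second singular value below 1e−3 of the first →
  "degenerate stain geometry" (e.g. a grayscale ramp).

The bundled default target profile was estimated once from a synthetic
mixed-tissue reference patch (LYM/STR/TUM region, seed 42) and frozen
as JSON package data, so normalization is reproducible offline.

## Tissue classifier

The classifier is a scikit-learn estimator: a 21-dimensional texture/
color descriptor per 224×224 patch (channel means and SDs, intensity
quantiles, dark/bright thresholded fractions with erosion variants,
two-scale gradient energy, block-mean dispersion, blue–red excess,
chroma spread), standardized and fed to a multilayer perceptron
(hidden layers 64/32, Adam, batch 32, learning rate 1e−3, 60 epochs,
seeded; a logistic-regression "linear" preset exists for quick runs).
The descriptor is nearly flip-invariant by construction; horizontal and
vertical flip augmentation is nevertheless applied during training.
The softmax output is the nine-class activation vector (sums to 1);
argmax ties break by fixed class order. Data are split 70/15/15
stratified by class with largest-remainder rounding.

Inference applies spatial pooling: the softmax is averaged over a 2×2
grid of 112-px sub-patches (configurable; 1 disables it). This is the
feature-classifier analog of a CNN's spatial pooling. On pure patches
it reproduces the full-patch prediction; on mixed tiles — the normal
case inside the sliding-window decomposition — it keeps the activation
vector close to area-proportional instead of letting global features
collapse the tile onto a single class, which is what makes region mean
activations track true area fractions.

This is deliberately a desk-scale architecture: the synthetic textures
are separable by design (each class documents a separating statistic in
`textures.py`), so a compact feature-based model reaches the accuracy
regime a deep CNN reaches on real patches. Passing tests therefore
show the *pipeline machinery* is correct; they say nothing about real
H&E generalization, which requires training a deep model on real data.

Evaluation utilities: confusion matrix (rows = truth; accuracy =
trace/total), and k = 25 random-subset one-vs-rest ROC statistics (AUC
on the class activation; sensitivity/specificity/PPV/NPV on argmax)
reported as median with 5th/95th percentiles across subsets.

## Tile decomposition

Regions (1,500×1,500 px at nominal 0.5 µm/px) are tiled with a 224-px
sliding window at stride 112 (50% overlap; the overlap degree is a free
choice, exposed in config) plus a flush-to-edge offset so borders are
covered. The region activation vector is the uniform mean over tile
activations (overlap de-weighting not applied). Rendered overlays
color each pixel by the palette-weighted average activation of the
tiles covering it. Patient-level vectors are the elementwise maximum
over a patient's regions; max-pooled vectors need not sum to 1.

## Deep stroma score

On a training cohort with per-patient pooled activations and a survival
endpoint (OS by default):

1. per class, a univariable Cox fit of the continuous activation gives
   HR_c (Efron tie handling via lifelines);
2. per class, the cutoff τ_c maximizes the Youden index
   J = sensitivity + specificity − 1 of "activation > τ" against the
   endpoint's end-of-follow-up event indicator (no time horizon is
   applied). Candidates are midpoints of consecutive sorted unique
   values; J-ties break toward the candidate closest to the median of
   the values, residual ties toward the smaller cutoff;
3. classes with HR_c > 1 are selected and
   S = Σ_{c selected} HR_c · 1[a_c > τ_c];
4. the training median m of S dichotomizes patients (high iff S > m,
   strict, so boundary cases default to low risk); m is frozen and
   reused unchanged on validation cohorts.

The published-2019 preset ships the printed per-class HRs (1.150,
0.015, 5.967, 1.226, 0.488, 3.761, 0.909, 1.154, 0.475), cutoffs
(0.00056, 0.00227, 0.03151, 0.00121, 0.01123, 0.02359, 0.06405,
0.00122, 0.99961) and median 8.347 as a frozen `ScoreModel`; the
weighted-sum reading of the score is corroborated by the fact that
8.347 equals the unique subset sum 5.967 + 1.226 + 1.154 (DEB + LYM +
STR) of the five HR > 1 weights.

High/low labels enter multivariable Cox models with UICC stage
(continuous 1–4), sex (0 = female, 1 = male) and age in decades;
per-stage models drop the stage covariate inside a stratum and report
"insufficient events" below 10 events rather than failing. Subjects
with missing endpoint data are excluded, never imputed. Comparator
scores (CAF-signature mean expression; pathologist stromal percentage)
are binarized at their own Youden-optimal cutoff before entering the
same multivariable model, and Pearson correlations among scores and
activations are reported.

## Synthetic data

* **Patches/regions.** Hematoxylin and eosin "concentration" fields per
  class archetype, rendered through the Beer–Lambert law with the
  nominal stain colors and additive Gaussian noise (σ = 2 intensity
  units), so synthetic images live in the OD geometry the Macenko
  estimator assumes. Regions are partitioned into 2–3 horizontal bands
  of vertical strips with largest-remainder widths (fraction error
  < 0.2 pp), giving rectangular, mostly class-pure blocks under the
  sliding window. Not modeled: scanner/batch effects beyond a global
  stain-color setting, nuclei-level morphology, photorealism.
* **Cohorts.** Each patient: a true activation vector from a sparse
  Dirichlet prior (concentrations 0.055–0.175, sum ≈ 0.61, TUM
  heaviest), stage uniform on 1–4, sex Bernoulli(0.5), age ~ N(68, 10)
  truncated to [30, 95]. Event times are exponential with hazard
  h0·exp(Σ β_c a_c + β_stage·stage + β_sex·sex + β_age·age/10),
  censoring uniform on [0, C]; defaults h0 = 0.01/month, C = 120
  months. The sparse prior reflects that a patient's pooled profile is
  dominated by one or two tissue classes (consistent with the very
  small published cutoffs) and gives the activations enough variance
  that a planted per-unit-activation log-hazard is identifiable at
  n = 2,000 (per-class SD ≈ 0.15–0.3, so SE(log HR) ≈ 0.1–0.17 at
  ~1,800 events). Simulation sizes used by the test suite — 50
  replicates of n = 2,000 for recovery, n = 1,000 for the end-to-end
  score, 200 patches/class and 50 regions for the imaging stages — were
  chosen as the smallest sizes at which these statistical properties
  are stable.

## Known limitations

* The classifier is not a CNN; transfer to real histology is out of
  scope and untested here.
* The Youden cutoff uses the end-of-follow-up event indicator; with
  heavy administrative censoring a time-horizon ROC would be more
  appropriate.
* Macenko estimation on a patch dominated by a single stain cannot
  recover the true two-stain geometry; the NNLS reconstruction keeps
  normalization well-behaved, but estimated profiles of such patches
  are not interpretable stain-by-stain.
* Whole-slide (pyramidal) inputs, automatic tumor-region detection,
  CMS subtype calling and gene-expression preprocessing are out of
  scope.
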