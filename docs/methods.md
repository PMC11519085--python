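# Methods

## Model

`pairlr` predicts a binary outcome Y ∈ {0, 1} for sample feature vectors
N ∈ ℝᵈ by pairwise comparison against T stored templates (M_I, y_I). The
pair vector is the signed difference V = M_I − N (an optional absolute-value
mode |M_I − N| is available for a pure distance reading). A binary pair
classifier g estimates the positive-pair probability
P_PP = Pr(y_I = Y | V). At inference the per-template sample-level score is

    s_I = P_PP        if y_I = 1
    s_I = 1 − P_PP    if y_I = 0

and P = (1/T) Σ s_I is the estimated event probability, thresholded at 0.5.

The naive form of the vote, "average of P_PP and (1 − P_NP)", is degenerate
for a binary pair classifier, because P_NP = 1 − P_PP makes both terms
identical and discards the template's own label. The rule above is the
reading under which the aggregate behaves as an event probability: a
positive-pair call from an event template and a negative-pair call from a
non-event template are both evidence *for* the event. It satisfies two
invariants the tests assert: flipping all template labels maps P → 1 − P,
and P is always in [0, 1].

**Assumptions.** The pair classifier must generalize over difference
vectors, which implicitly assumes approximate translation invariance of the
class geometry (only differences, not absolute positions, are seen). The
default Gaussian naive Bayes additionally assumes conditional independence
of the pair-vector coordinates — reasonable after correlation filtering,
which is one reason the PCC step precedes it.

## Pipeline and parameters

`fit_pipeline` chains: normalize → redundancy-reduce → screen →
select templates → build pairs → fit pair classifier. All data-dependent
statistics are fitted on the training partition only and frozen in the
model; `training_sample_ids` records exactly which samples contributed, and
cross-validation asserts the validation fold is disjoint from it.

| parameter | default | notes |
|---|---|---|
| `normalization_scheme` | `unit_zero_center` | x′ = (x − mean)/‖x − mean‖ per feature. "Unit" is read as division by the per-feature Euclidean norm over training samples (not min–max): it is the reading consistent with composing "unit" and "zero-centre" into one scheme. Constant features map to zero with a scale fallback of 1 and are flagged. |
| `reduction` | `pcc` | Greedy scan in feature order; a feature is kept iff \|r\| ≤ threshold against every kept feature. Deterministic, idempotent, sample-order invariant. |
| `pcc_threshold` | 0.99 | Removes only near-duplicate features; no published value exists, so the filter is deliberately conservative and the screener does the real selection. |
| `screener` | `anova` | Per-feature one-way F score (equivalently the squared pooled-variance t statistic for two groups). "ANOVA" screening is implemented per-feature — the standard select-K-best construction — not as a true MANOVA, which could not produce a per-feature ranking. |
| `n_features` | 12 | The selected model size in the motivating study (ten radiomics + two clinical features). |
| `classifier` | `gaussian_nb` | Ten families available (SVM linear/RBF, LDA, logistic, kNN, decision tree, random forest, AdaBoost, Gaussian process); sklearn estimators behind a thin probability interface. The named four are from the study; the remaining slots are standard choices. |
| `n_templates` | 7 | Split across classes by largest-remainder apportionment with ≥ 1 per class (45/46 training counts → 3 event / 4 non-event). |
| `template_strategy` | `medoid` | Per class, the samples minimizing the summed Euclidean distance to all same-class samples, ties broken by sample id. A deterministic stand-in for the expert choice of "representative cases"; `manual` accepts explicit ids, `random` is seeded. |
| `split_ratio` | 0.7 | Stratified largest-remainder split: n = 130 with 64 events → 91 train (45 events) / 39 test. |
| `cv_folds` | 5 | Stratified; n = 91 gives fold sizes {19, 18, 18, 18, 18}. |
| `decision_threshold` | 0.5 | P = 0.5 ties go to class 1 (the ≥ rule); the raw probability, not the hard class, feeds ROC/calibration/DCA. |

Screening rank ties break lexicographically by feature name, so rankings are
pure functions of the data regardless of column order. Relief follows the
classic binary nearest-hit/nearest-miss weight update with per-feature
range-normalized differences, visiting every training sample once in seeded
random order; a class with a single member contributes nothing (logged).
RFE uses an L2-regularized logistic base model because naive Bayes exposes
no coefficient magnitudes, eliminating one feature per step.

Self-pairs (a template differenced with its own row) are excluded from
training: they are zero vectors that would act as degenerate, perfectly
confident positive pairs and bias the pair classifier. Templates are drawn
from, and stay inside, the training partition — the only leakage-safe
arrangement.

`grid_optimize` scores every scheme combination by mean CV-validation AUC
(ties: fewer features, then lexicographic config), records failed cells
rather than aborting, and refits the winner on the full training table. The
default grid (3 normalizations × {pcc, pca} × 3 screeners × 1–20 features ×
10 classifiers) is what the accompanying study compared; tests and the
acceptance script use small sub-grids since the full product is a
long-running batch job.

## Evaluation statistics

* **AUC** is the Mann–Whitney concordance probability (ties half-credited),
  computed via `sklearn.roc_auc_score` and cross-checked in the tests
  against brute-force pair counting. The CI is a stratified percentile
  bootstrap (1000 resamples within each class) — the interval method behind
  published radiomics AUC intervals is typically unstated, and the
  percentile bootstrap is the assumption-light default.
* **Hosmer–Lemeshow** bins by deciles of predicted risk with tied edges
  merged (fewer groups ⇒ fewer degrees of freedom, df = groups − 2), with
  the event-count variance form (O − E)²/(E(1 − E/n_g)).
* **Decision curves** use net benefit TP/n − (FP/n)·p_t/(1 − p_t) on the
  grid p_t = 0.01…0.99, against treat-all and treat-none policies. No
  smoothing.
* **Cohort baseline tables** default to Pearson chi-squared *without*
  continuity correction: published two-cohort comparison tables of this
  kind (including cells with expected counts < 5) verify against the
  uncorrected statistic, so the expected-count rule is surfaced as a
  warning, not an automatic switch to Fisher's exact (available by flag).
  Continuous variables use the two-sided Mann–Whitney U with normal
  approximation and tie correction.
* **ICC** is fixed to ICC(2,1) — two-way random effects, absolute
  agreement, single rater — with F = MSR/MSE on (n−1, (n−1)(k−1)) df and
  McGraw–Wong F-distribution confidence bounds. Absolute-agreement ICC is
  invariant to an affine transform applied to *both* readers but not to a
  single-reader shift; the tests assert both directions. The implementation
  is a direct mean-squares computation, cross-checked against pingouin.
* **Dice** follows 2|A∩B|/(|A|+|B|) with the both-empty case defined as 1.0
  (flagged), since two readers who both find nothing agree.

## Synthetic data

`generate_cohort` emulates the study cohort: by default n = 130 with
exactly 64 events (prevalence fixed by count, not Bernoulli draws, so
small-cohort tests are stable), 200 radiomics features in equicorrelated
Gaussian blocks of 10 at ρ = 0.8 (mimicking the strong within-family
correlation of real radiomics panels that motivates the PCC filter), 5
informative features spread one-per-block with a standardized mean
difference of 1.0, plus a continuous and a 4-level ordinal clinical
covariate built from a shifted latent Gaussian cut at its quantiles.
Ordinal clinical variables are pre-encoded as numerics; the pipeline treats
all features as continuous.

What the generator does **not** emulate: heavy-tailed and bounded feature
distributions, scanner/batch effects, label noise, missingness, and
non-linear feature-outcome relationships. Passing tests therefore
demonstrate correctness of the machinery and sane behaviour under the
assumed Gaussian geometry — not clinical performance on real CT radiomics,
which can only be established on real data.

`generate_mask_pair` produces an ellipsoid mask and a centre/radii-jittered
copy as a two-reader fixture; expected Dice decreases monotonically in the
jitter scale.

## Numerical choices

* Gaussian NB variance floor: sklearn's `var_smoothing` (1e−9 of the largest
  feature variance) keeps zero-variance pair dimensions finite.
* PCA components carry a deterministic sign convention (largest-magnitude
  loading positive); requests beyond the rank bound are truncated with a
  warning.
* Model files are JSON with a `format_version` field; the Gaussian NB
  default is stored as explicit per-class means/variances/priors, other
  classifier families as an embedded base64 pickle payload. Serialization
  uses sorted keys, so refitting with the same data, config and seed
  reproduces the file byte-for-byte.
* All randomness (splits, CV shuffling, Relief visit order, bootstrap,
  stochastic classifiers, generators) flows from explicit integer seeds.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 130-sample, 202-feature synthetic cohort (about 25 ms per fit), 20
seeds per stochastic experiment, exhaustive voting-rule enumeration up to 4
templates at probability step 0.25 (11 110 cases), and brute-force metric
oracles at n = 25–200. These sizes give stable statistics while keeping the
whole suite under ten seconds.

## Known limitations

* Binary outcomes only; no survival-time modelling of recurrence.
* Inputs begin at the feature table: CT image handling and radiomics
  feature extraction are out of scope.
* The pair classifier sees each training sample in up to T pairs, so pair
  observations are not independent; CV on *samples* (never on pairs) is the
  honest error estimate and is what `crossvalidate` implements.
* Exactly two readers for ICC; no surface-distance mask metrics.
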