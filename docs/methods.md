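# Methods

## Problem setting

Radiomics-based early detection of lung cancer asks a classifier to predict
the eventual (endpoint) diagnosis of a pulmonary nodule (PN) from features
extracted from a CT scan taken while the nodule still looks benign,
probably benign, or indeterminate to a radiologist.  Two obstacles dominate:

1. **Class imbalance.** Malignancy is rare among early-development nodules,
   so the training signal is thin.  A remedy is to *augment* the training
   set with scans of later-development nodules whose diagnosis has been
   confirmed (benign by resection/biopsy, malignant by PET-CT/biopsy).
2. **Acquisition variability.** Radiomic features depend on how the scan
   was acquired — contrast enhancement (CE), kilovoltage peak (KVP), focal
   spot size, scanner manufacturer.  These batch effects must be removed
   (harmonized) before features are biologically meaningful.

The two remedies interact: CE is administered preferentially when there is
clinical concern, so CE is *confounded* with malignancy in
later-development data, and contrast physically accumulates more in tumors
than in benign tissue, so the *size* of the CE effect also differs by
biology.  Harmonizing augmented training data without acknowledging
biology can therefore do more harm than good.  This package implements and
compares the three ways of applying harmonization to an augmented training
set, and the machinery to measure their consequences.

## ComBat model

For feature `g` of scan `j` acquired at batch level `i` of one acquisition
parameter,

```
y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg ,
```

with `alpha_g` the grand mean, `X_j beta_g` an optional categorical
covariate term, `gamma_ig` an additive and `delta_ig` a multiplicative
batch effect, and `eps` mean-zero noise.  Fitting is the standard
parametric empirical-Bayes recipe: OLS on the batch one-hot plus
reference-coded covariate design (the weighted batch-effect identifiability
constraint `sum_i (n_i/N) gamma_ig = 0` is implicit in taking the grand
mean as the count-weighted average of batch intercepts); pooled residual
variance over all N scans (divided by N, not N−p); standardization;
per-batch sample moments (variance with ddof=1); method-of-moments normal /
inverse-gamma hyperpriors, with the inverse-gamma moment match
`a = (2 v + m^2)/v`, `b = (m v + m^3)/v` for `m, v` the across-feature mean
and variance of the raw scale estimates; and iteration of the conditional
posterior means to convergence.

Numerical conventions follow the reference implementation exactly so that
the two agree to floating-point error (the test suite asserts elementwise
agreement with R's `sva::ComBat` at 1e-6 on random fixtures): convergence
is the reference's *maximum relative change* criterion at 1e-4 (not an
absolute tolerance) with a 1000-iteration cap; features with zero variance
inside any batch level are passed through unadjusted rather than failing
the whole fit; fitting refuses designs with fewer than two batch levels,
any level with fewer than three scans, or a covariate confounded with the
batch (rank-deficient design).

Application to unseen scans uses only training-fitted statistics
(`alpha, beta, sigma^2, gamma*, delta*`), so a single test scan can be
harmonized and the result for one scan never depends on which other scans
arrive with it.  The covariate term is reconstructed at application time
from the scan's known dataset label (never its endpoint), using the stored
level registry and reference level; the alternative of applying grand
means only would discard the dataset intercepts and is not what the
from-training application of the reference implementation does.

## OPNCB and the three modes

With several acquisition parameters, ComBat is applied sequentially, one
parameter at a time, each step consuming the previous step's output.  The
order matters because scale corrections do not commute; OPNCB chooses it
by exhaustively fitting every permutation (4! = 24 at the default four
parameters) and keeping the one whose harmonized output leaves the most
features acquisition-independent under the Kruskal–Wallis screen below.
Ties break lexicographically, a permutation whose intermediate fit fails
is disqualified rather than aborting the search, and a parameter left with
a single level is skipped with a log entry.

The three modes differ in what the chain knows about biology:

* **collective** — one chain on all training scans, no covariates;
* **covariate** — one chain with the dataset label (early /
  benign-augmentation / malignant-augmentation) as a categorical
  covariate: dataset-specific intercepts, shared corrections;
* **separate** — three chains fitted independently per dataset, each with
  its own permutation search and its own re-application of the min-3
  exclusion rule.  Test scans — always early-development — are routed
  through the early chain only, so no endpoint knowledge ever touches the
  test path.

Whether the original procedure re-optimized the permutation per subset in
separate mode, and whether the screen was evaluated per permutation on the
full chain or incrementally, are open details; this implementation
optimizes per subset and scores full chains.  For the early-development
chain the screen proper is undefined (early data mix undeveloped benign
and malignant tissue), so its order is chosen by the same Kruskal–Wallis
machinery applied across parameter levels within the early scans alone.

Exclusion rules: a (parameter, level) group with fewer than 3 training
scans cannot support a fit, so such scans are removed iteratively until a
fixed point (removals can cascade); the rule is applied marginally per
parameter, not to joint protocol combinations.  A test scan carrying a
level absent from its chain has no estimator and is excluded; a trial
whose test set empties this way is abandoned.

## Acquisition-dependence screen

For each feature, each parameter, and each augmentation subset (benign /
malignant separately — correct distributions must be acquisition-stable
*within* a biology, while the two biologies may legitimately differ), scans
are grouped by parameter level and compared with the tie-corrected
Kruskal–Wallis test against a chi-square null.  A feature is acquisition
dependent if any tested cell has p ≤ 0.05 (raw; no multiplicity
adjustment inside the screen — the Holm correction applies only to
between-method comparisons).  Levels with fewer than 2 scans are dropped
from a test; a test left with fewer than 2 levels is untestable and never
implies dependence.  A constant feature gets p = 1: it cannot exhibit
acquisition dependence.

The screen's null validation partitions "uniform groups" (scans sharing
every parameter level, size ≥ 8) randomly into two pseudo-levels and runs
the screen on that synthetic parameter; each feature then faces at most
two tests at alpha = 0.05, so the expected independent fraction under the
null is at least 0.95² ≈ 0.9025.  The suite asserts the conservative
≥ 0.90 bound and reports the measured value (≈ 0.95 on the default null
cohort).

## Detection pipeline

The early-development cohort is split by a grouped (patient) stratified
(scan-level endpoint) 5-fold scheme, repeated 10 times → 50 trials.
Augmentation scans from any patient in a trial's test set are unavailable
to that trial.  Augmentation is cumulative: each trial owns one seeded
shuffle of its available augmentation scans, and the fraction-f training
set takes the first ceil(f·n) entries, so smaller fractions nest inside
larger ones.  The seed schedule (master seed → per-trial seed → shuffle)
is recorded in each split for exact replay.

Within a trial: rare-protocol exclusion → OPNCB in the requested mode →
screen on the harmonized augmentation training data (the un-augmented
baseline skips the screen — there is nothing to screen) → standardization
to zero mean / unit variance on training statistics → LASSO (alpha = 0.05,
intercept, selection = |coef| > 1e-10) → linear SVM (C = 1, malignant
positive).  Test scans are excluded for unseen protocols, harmonized from
training, standardized with the training scaler, and scored; class metrics
use the SVM decision boundary (score 0) with no threshold tuning;
weighted accuracy is (sensitivity + specificity)/2.  A trial with no
selected features, or whose harmonization or test application fails, is
skipped with a recorded status and excluded from aggregates.

Learning curves aggregate mean test ROC-AUC per (mode, fraction) over OK
trials with t-distribution CIs and fit `AUC = a + b ln(f)` over the f > 0
cells by least squares (the baseline is plotted but not fitted; a
constant response is reported NOT_FIT).  Method comparisons use DeLong's
paired-ROC test per trial (restricted to the test scans both modes
retained), Holm–Bonferroni-adjusted across the three method pairs within
each trial; Wilcoxon signed-rank across trials where all compared models
ran; t CIs for continuous metrics and exact Poisson CIs for
selected-feature counts.  DeLong is implemented from the structural
components (placement values); the test suite checks its variance against
a stratified bootstrap.

## Synthetic cohort generator

Real feature tables for this problem are restricted, so the generator
produces cohorts with the structure the analysis assumes.  Feature model
for scan `s`, feature `g`:

```
y_sg = mu_g + nu_g 1[later] + kappa_g rho(s) 1[malignant]
     + sum_p gamma[p, level_p(s), T(s), g]
     + (prod_p delta[p, level_p(s), T(s), g]) eps_sg
```

* `T(s)` is the tissue context: "early" for early-development scans
  regardless of endpoint (an early malignant PN has not yet developed the
  tissue properties that drive context-specific acquisition effects — a
  config switch lets early malignant scans take the malignant context
  instead, default off); "benign"/"malignant" for augmentation scans.
* `nu_g` (development shift, ~50% of features, 0.5–1.5 SD) separates
  later-development from early scans independent of endpoint — growth and
  density changes that any later-development nodule shows.
* `kappa_g` (class signal, 8 features, 1–2 SD, random sign) separates
  malignant from benign; `rho(s) = rho = 0.4` attenuates it in
  early-development scans, 1 otherwise.
* Each acquisition parameter carries a *shared* effect (identical across
  contexts) and, when `biology_dependent=True`, a context-specific *extra*
  (additive shifts add, scales multiply).  Defaults: CE — shared on 50% of
  features plus a strong malignant-context extra on 30% (contrast
  accumulates in tumors); focal spot — shared only (50%); KVP — weak
  shared (10%); manufacturer — malignant-context extra only (45%).
* Protocol frequencies are dataset-specific with CE at 0.1 / 0.2 / 0.7 in
  the early / benign-augmentation / malignant-augmentation datasets, which
  reproduces the CE-malignancy confounding.
* Noise is iid N(0, 1) per feature; multiplicative effects compose by
  product, additive by sum, matching ComBat's per-parameter
  location–scale model applied sequentially.  No per-patient random
  effect by default (the ComBat model has none).

Default counts reproduce the study shape exactly at the scan level: 187
early scans (16.6% malignant; 19.5% of 82 nodules), 36 benign and 189
malignant augmentation scans over 58 + 21 + 58 patients, with 16 malignant
and 5 benign early nodules re-scanned in the augmentation datasets
(follow-ups), so the pooled pool is 53.4% malignant over 412 scans.
Patient/nodule totals are approximate when follow-up patients overlap;
scan and nodule counts are exact.  All protocol frequencies and effect
magnitudes are invented defaults (the real per-protocol frequencies are
not public) and are user-overridable.

Every cohort ships with a `GroundTruth` ledger (true per-context effects,
signal set, noise seed) from which the feature block is exactly
reconstructable, enabling parameter-recovery tests.

### What the generator does and does not emulate

It encodes the hierarchy, prevalences, confounding, and biology-dependent
location–scale acquisition effects.  It does **not** emulate inter-feature
correlation (real radiomic features are highly collinear), non-Gaussian
feature marginals, continuous acquisition parameters (slice thickness,
kernel), within-patient correlation of protocols across follow-ups, or
lesion-size trajectories.  Passing tests therefore demonstrate that the
algorithms behave correctly under the assumed generating model, not that
the clinical effect sizes are reproduced; the directional findings (which
harmonization mode preserves signal) are the claims the synthetic
experiments support.

## Numerical and design choices

* Acquisition levels are opaque categorical strings everywhere; no numeric
  ordering is used (KVP "100" vs "120" are labels).
* Missing acquisition metadata is a validation error; scans are excluded,
  never imputed.
* Covariate reference level: the most frequent training level (ties:
  lexicographic).  Harmonized output is invariant to this choice; it is
  recorded for exact test-time design reconstruction.
* Screen `min_group_n = 2` (the KW statistic is defined at 2 but
  unstable; small-group tests are logged).
* The directional experiment in the acceptance suite uses the default
  cohort shape, 50 trials, three modes, full augmentation — about four
  minutes on one CPU; unit tests use scaled-down cohorts (the same
  generator at fractions of the default counts).
* Degenerate cases: a test set left with one class yields undefined AUC
  (dropped from aggregates with a log entry); identical paired score
  vectors give DeLong p = 1; an all-constant feature block yields an
  identity ComBat model rather than an error.

## Known limitations

* Parametric EB priors only; the nonparametric ComBat variant and
  continuous covariates are out of scope.
* The permutation search is exhaustive, practical for ≤ 5 parameters by
  design; no greedy fallback is provided.
* The screen's per-feature dependence flag takes up to 8 raw tests per
  feature, so its false-positive rate under a global null is well above
  5% per feature (≈ 1 − 0.95^8); this matches the procedure it implements,
  which is defined on raw p-values.
* Under collective harmonization on confounded data, mean test AUC is
  estimated over the subset of trials that could train a model; with very
  few informative features surviving that screen this subset can be small.
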