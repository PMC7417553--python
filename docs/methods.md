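# Methods

`simguided` implements a simulation-guided protocol for building and
validating machine-learning pipelines on multimodal clinical cohorts with
modest sample sizes: algorithms and settings are selected on simulated
cohorts that mimic the real data's shape, dimensionality and missingness,
and only the selected few are ever evaluated on target data. This note
documents the models, the numerical conventions, and the design choices
made where the design was genuinely open.

## The latent cohort model

Each subject i carries an unobserved one-dimensional trait z_i that
drives both features and outcome. Two restrictions embody the two
standing hypotheses about the structure of treatment response:

- **cluster**: z_i ∈ {−1, +1} with P(+1) = mixing proportion (default
  0.5) — discrete subgroups;
- **spectrum**: z_i ~ N(0, 1) — a continuum.

Feature j of submodality s is x_ij = w_j z_i + ε_ij with loadings
w_j ~ N(0, 1) drawn once per fixture and frozen, and Gaussian noise ε.
Both restrictions are deliberate simplifications: real cohorts are not
one-dimensional, and the simulator makes no attempt to reproduce
between-feature covariance, scanner or site effects.

**SNR convention.** SNR_dB = 10·log₁₀(Var_signal / Var_noise), computed
over *all* feature entries of the dataset pooled together. The noise
matrix is rescaled after sampling so the realized ratio equals
10^(SNR_dB/10) exactly (the acceptance suite checks within 1%). A
consequence worth knowing: because the convention is dataset-level, the
total class separation grows with feature count as 2·√(p·10^(SNR/10))
for cluster data, so the *difficulty* of a given dB level depends on the
layout's dimensionality. Experiments that probe the "all algorithms at
chance" regime therefore use a deliberately low-dimensional layout (see
Problem sizes).

**Outcomes.** `cluster_label`: label = 1(z > 0). `binary_threshold`:
label = 1(z > median z), strict inequality. `linear_response`:
response = z + noise with Var(z)/Var(noise) at the spec's SNR, giving the
analytic R² = SNR/(SNR+1).

**Missingness grafting.** A boolean mask per submodality (True =
missing), extracted from a reference cohort, is applied entry-wise to
simulated data; when the mask's subject count differs from the cohort's,
mask rows are resampled with replacement (seeded). The reference fixture
is a 289-subject, 5-modality tree (cognition, MRI, electrophysiology,
psychopathology, perinatal register) split into 26 named submodalities,
with block-wise holes (10–25% of subjects missing whole blocks such as
MRI or register records) plus 5% randomly missing cells. The per-
submodality feature counts are configurable stand-ins, not measured
values.

**Grid.** The default grid sweeps SNR from −20 to +20 dB in steps of
5 dB × {cluster, spectrum} × 10 generator seeds = 180 datasets.

## Preprocessing: train-only fit/apply

Imputation and standardization follow a strict fit/apply contract: every
parameter derives from training rows only, and `apply_*` never updates
state. Parameters serialize to JSON and hash to a digest, which is what
the leakage audit compares.

- **Median imputation**: per-feature median of observed training values.
- **PPCA imputation**: x = Wz + μ + σ²-noise with latent dimension
  k = min(5, p−1) by default, fitted by EM in which both the latent
  factors and the missing cells are treated as missing data, so the
  observed-data log-likelihood is provably non-decreasing (asserted by a
  test). Initialization: SVD of mean-imputed data plus a tiny seeded
  jitter; convergence at relative log-likelihood change < 10⁻⁶ or 500
  iterations; σ² floored at 10⁻¹². Missing cells are imputed by their
  posterior mean given the row's observed entries.
- **Standardization**: training mean and *sample* sd (n−1 denominator).
  A zero-variance training feature gets sd = 1 (centered only), keeping
  block shapes stable across CV replications.
- Imputation operates per submodality block, consistent with late
  integration; covariates are assumed complete.

## Nested cross-validation and late integration

The outer loop draws `n_replications` random 75/25 splits (test size =
round-half-up of n/4), stratified by outcome or by cohort. Within a
replication, each submodality block (its features plus the appended
covariate columns — age, and one-hot sex/cohort/handedness) is imputed,
standardized, and modelled independently; the inner loop is 3-fold CV.
Subjects whose entire block is missing contribute no training row and
receive no prediction from that submodality. Test predictions are
combined by late integration:

- **mean**: unweighted average of available submodality class-1 scores
  (or regression values), threshold 0.5 — a tied score of exactly 0.5 is
  assigned class 1;
- **weighted**: weights proportional to each submodality's inner-CV
  score — excess BACC over 0.5 for classification, 1 − NMSE for
  regression, clipped at 0 — renormalized over the submodalities
  available for that subject, falling back to the mean scheme when all
  weights vanish.

A replication whose training split lacks an outcome class is redrawn
with a logged sub-seed (up to 20 attempts). All seeds derive from one
master seed hashed with stage names and indices, so runs are reproducible
bit-for-bit; per-replication digests of every fitted parameter (imputer,
standardizer, chosen hyperparameters, ensemble weights) form the leakage
audit trail.

## Learners

**Registry.** A frozen inventory of 21 classification configurations
from 8 families (logistic regression, Gaussian naive Bayes, random
forest, decision tree, gradient-boosted tree ensemble, SVM with
linear/polynomial/RBF kernels, k-NN, and an SGD-based linear classifier
for high-dimensional data) and 32 regression configurations from 9
families (linear/ridge regression, SVR with three kernels, Gaussian
process, regression tree, Gaussian GLM, gradient-boosted and AdaBoost
ensembles, random forest, lasso, and L1-regularized SVR). Each family
appears in a defaults variant and (for most) a tuned variant with a
bounded search space; the exact hyperparameter inventories are this
package's reconstruction — the frozen contract is the counts and family
coverage, guarded by tests.

**Tuning.** `bayes_opt` configurations are tuned by sequential
model-based optimization: iteration 1 evaluates the declared defaults
(so the incumbent can never be worse than the defaults), 20% of
iterations explore uniformly at random, and the remainder maximize
expected improvement under a Matérn-5/2 Gaussian-process surrogate over
the unit cube (log-scaled axes where declared), with 25 evaluations by
default. The objective is the mean held-out inner-CV score: BACC for
classification, negative NMSE for regression.

**Auto-ensemble.** Candidates (configuration + hyperparameters) are
sampled from the registry and scored on held-out inner-CV predictions
until a budget is exhausted; the ensemble is then built by greedy forward
selection *with replacement* on those held-out predictions, stopping
early when no candidate improves the bag, capped at the maximum ensemble
size; weights are selection frequencies and members are refitted on the
full training data. The budget is a candidate-evaluation count by
default — 20/60/180 evaluations map one-to-one onto the familiar
training-time grid of 20/60/180 s, which is hardware-dependent and
therefore unsuitable as a reproducible default; a wall-clock mode is
available for parity.

## Performance measures and comparisons

- **BACC** = (sensitivity + specificity)/2; 0.5 at chance under any
  class imbalance.
- **NMSE** = MSE / Var(y_true), with the *population* variance of the
  evaluation split, making "predict the test mean → NMSE = 1" an exact
  identity. This convention is documented prominently because it is the
  one under which the chance level is exactly 1.
- **Aggregation**: mean across replications with a 95% percentile CI
  (2.5th/97.5th, linear interpolation). Percentile intervals reproduce
  the degenerate [50.0, 50.0] interval a constant classifier yields.
  Significance = the CI excludes the chance level on the favorable side.
- **Pairwise comparison**: two-sided paired sign-flip permutation test
  on per-replication score differences (10⁴ seeded permutations, add-one
  estimator). Chosen over a t-test because it respects the pairing and
  assumes no distributional form.

## Ranking and transfer validation

Per-configuration scores are averaged over grid cells inside a low-SNR
window (default [−20, 0] dB — the range where configurations are
distinguishable; at the extremes all perform equally well or poorly).
Best = max, poorest = min, median = the lower-middle order statistic on
even counts. Validation reruns the three selected configurations on
target data and flags whether their weak order (ties allowed) is
preserved, attaching pairwise permutation p-values. The package's
self-consistency experiment performs selection on one seed set and
validates on five fresh cohorts at a matched SNR, requiring preservation
in the majority of trials.

## Problem sizes used by the shipped experiments

All experiment defaults are frozen in `simguided.experiments`:

- Chance calibration: 10⁴ labels × 1000 replicates (BACC); n = 500
  (NMSE identity).
- SNR sweep: 5 SNRs (−20…+20 dB) × 2 variants × 3 generator seeds,
  120 subjects, 4 submodalities × 3 features, 10 outer replications,
  three defaults-mode classifiers.
- Extremes: the full 21-config registry at ±20 dB on 120-subject,
  2-submodality × 1-feature cohorts, 10 replications per cohort, with
  the −20 dB scores pooled over 3 independently generated cohorts (+20 dB
  uses one cohort: a best-configuration maximum on trivially separable
  data needs no pooling); 4 tuning evaluations. Two
  deliberate design points: (i) low dimensionality — with the
  dataset-level dB convention the Bayes-optimal BACC at −20 dB is
  Φ(√(p·0.01)) ≈ 0.56 at p = 2, so the low-SNR end is genuinely
  unlearnable while +20 dB remains trivially separable; (ii) pooling
  across cohorts — replications of a single finite cohort are
  correlated (they share its idiosyncratic noise alignment), so a CI
  built from one cohort alone can sit entirely off chance by cohort
  luck; pooling mirrors the multi-seed grid the sweep itself uses.
- Leakage audit: three independent one-replication runs with test rows
  overwritten by constants; digests must be bit-identical.
- Ranking transfer: selection on SNR {−10, −5, 0} × 2 seeds with five
  defaults-mode classifiers; validation on five fresh cohorts at 0 dB.
- PPCA oracle: 200 × 20 rank-1 data at +20 dB with 10% holes; the
  oracle is the noiseless rank-1 component (what a full-data SVD
  reconstruction recovers).

## What the simulations do and do not show

Passing these suites shows that the machinery is sound: no leakage, a
calibrated chance level, SNR-monotone accuracy, selection that transfers
across simulation seeds, and imputation that exploits low-rank structure
when it exists. It does not show that any particular real cohort is
predictable — real data have correlated features, site effects,
non-Gaussian noise and outcome structure that the one-dimensional latent
model deliberately omits. The framework's claim is narrower: whatever
performance is achievable, this protocol estimates it without optimistic
bias.

## Known limitations

- Multiple imputation and imputation with a reject option are not
  implemented.
- The weighted integration scheme uses inner-CV scores as weights; no
  stacking or meta-learner is provided.
- The auto-ensemble samples hyperparameters randomly within each
  candidate's space rather than running a joint Bayesian search over the
  combined configuration space.
- PPCA EM is O(n·p·k) per iteration with a Python loop over rows;
  adequate for cohort-sized blocks, not for omics-scale matrices.
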