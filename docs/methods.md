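# Methods

## Model and procedure

`mivip` estimates the relative importance of p mixed-type predictors for a
continuous outcome under missing data. The procedure treats the importance
score itself as the estimand of a multiple-imputation analysis: impute M
times, estimate the importance of every variable within each completed
dataset, and pool the estimates with a Rubin-style variance combination.

**Imputation.** Missing cells are filled by iterative chained forests.
Each run initializes missing continuous cells with the column mean and
categorical/genotype cells with the mode, then cycles variables in order
of increasing missingness, refitting a bootstrap forest of the remaining
predictors on the observed rows of the target column and predicting its
missing entries. Cycling stops when the normalized change in the imputed
values (sum of squared differences over sum of squares for continuous
variables; fraction of changed labels for categorical ones) increases for
the first time for every variable type present — the previous iteration's
values are kept — or at a hard cap. Stochasticity in the bootstrap makes
the M runs genuinely different, which is what feeds the between-imputation
variance downstream. The outcome is excluded from the imputation models by
default so importance scores cannot leak the outcome through imputed
covariates (`use_outcome=True` reverses this).

**Forest importance.** Per imputation a bagged ensemble of CART regression
trees is fit (random feature subset at each split, bootstrap bag recorded
per tree). For variable j, tree b, and replicate k = 1..K, the values of
x_j are permuted within tree b's out-of-bag rows, the tree's OOB MSE is
recomputed, and the increase over the unpermuted per-tree OOB MSE is
recorded. theta_hat_j is the mean of the K·B increases. The per-imputation
standard error s_j is the standard deviation over trees of the K-averaged
per-tree increases divided by sqrt(B) — the convention behind the usual
scaled forest importance, and the only within-imputation dispersion
available at this granularity. Permutation streams are keyed by variable
name, so results do not depend on evaluation order. A variable constant
within every OOB sample produces exactly zero increases (theta = 0,
se = 0), with no special-casing.

**Pooling.** theta_bar, W_bar (mean squared SE), B_bar (between-imputation
variance, denominator M−1), V = W_bar + (M+1)/M · B_bar, and the
standardized score T = theta_bar / sqrt(V); T is defined as 0 when V = 0
(identically zero importance). Ranks are computed inside each imputation
(rank 1 = most important; exact ties get average ranks, which only occur
for all-zero variables in practice), then summarized across imputations by
the mean and the empirical 2.5/97.5 percentiles (linear interpolation).
Full precision is kept internally; half-up rounding to integers happens
only at reporting time, so a variable ranked first everywhere reports the
degenerate interval (1, 1).

**Boosting influence.** Stochastic gradient boosting on squared error
(depth-limited trees, row subsampling). The tree count is the minimizer of
the fold-averaged k-fold CV deviance curve; the final model is trained on
all rows and truncated there. Relative influence: per tree, a variable's
squared importance is the sum of weighted squared-error decreases over the
internal nodes splitting on it; squared importances are averaged over the
retained trees, square-rooted, and rescaled to sum 100. The square root
matches the "scaled relative importance" reporting convention;
`scale="squared"` reproduces the plain normalized squared influences
(62.5/37.5 instead of 56.35/43.65 on the two-tree worked example).

**Consensus.** Each method's M × p matrix is mapped through
(x − min_avg)/(max_avg − min_avg), where the anchors are the minimum and
maximum across-variable *average* importance of that method. Individual
cells may leave [0, 1] and are deliberately not clamped — clamping would
bias the subsequent average. The two normalized matrices are stacked
(2M rows) and averaged per variable; with equal M this equals averaging
the two methods' normalized means, but the stacked form preserves
dispersion for plotting. Anchors are computed once from across-imputation
averages, not per imputation.

**Genetics.** MAF = (het + 2·minor hom)/(2n), auto-reoriented to ≤ 0.5.
The HWE screen is a 1-df chi-square against (p²n, 2pqn, q²n) with q
estimated from the same counts, no continuity correction; monomorphic
input raises instead of fabricating a p-value. The GRS is the unweighted
sum of risk-allele counts over the panel; SNPs with missing genotypes are
excluded from the sum and surfaced in `n_missing_snps` rather than
mean-imputed. In the pipeline, subjects with an incomplete panel get a
missing GRS that the imputation stage fills, and the raw SNP columns are
dropped before modeling (GRS-only, configurable), so a study's "11 SNPs"
enter the models as one genetic predictor.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| M | 100 | imputations; studies of this design commonly use 100, tests and the demo use 5 |
| RF n_trees (B) | 500 | trees per forest |
| RF n_permutations (K) | 5 | OOB permutations per variable per tree |
| RF mtry | p/3 (≥1) | split candidates, regression-forest convention |
| GBM max_trees | 5000 | boosting iterations before CV truncation |
| GBM learning_rate | 0.01 | shrinkage |
| GBM bag_fraction | 0.5 | row subsample per tree |
| GBM interaction_depth | 3 | tree depth |
| GBM cv_folds | 5 | folds for the deviance curve |
| imputation n_trees | 100 | trees per per-column forest (missForest default) |
| imputation max_iter | 10 | hard cap on chained cycles |
| k_top | 30 | variables shown in plots |

Ordinal encoding is used for categorical predictors in the tree models and
genotypes enter as risk-allele counts (0/1/2); categorical columns are
permuted as whole label columns in the importance step, avoiding
encoding artifacts.

## Synthetic cohorts

The generator emulates the statistical skeleton of a multidomain pediatric
obesity survey: mixed continuous/categorical/genotype predictors with
domain tags, an additive linear outcome on *standardized* encodings
(z-scored continuous values and category codes, raw 0/1/2 risk counts)
plus Gaussian noise, per-variable missingness (MCAR, or MAR with a
logistic dependence on one complete covariate, intercept calibrated by
root-finding so the marginal rate matches the declared rate), and an
11-SNP panel whose simulated minor-allele frequencies follow a published
childhood-obesity panel. Standardizing the encodings makes |effect|
comparable across types, so the ground-truth ranking (`oracle_ranking`,
descending |effect|, lexicographic ties) is well defined.

Two fixtures are provided. `demo_spec` (the test default): 300 subjects,
50 predictors (33 continuous, 6 categorical, the 11-SNP panel), three
planted continuous effects of 2.0/1.5/1.0 standardized units, noise SD 2.4
(explainable variance near one half, in the range such cohort models
attain), 10% missingness on every predictor. `study_spec`: 221 subjects
and the full domain mix (3 characteristics, 11 SNPs → 1 GRS, 24 activity,
80 diet, 39 pregnancy/birth, 43 social/health variables → 190 modeled
predictors), questionnaire-style missing rates of 6–10% and 2% on
genotypes, and planted effects that echo the kinds of variables such
studies rank on top (energy balance, parental BMI, an activity score, a
GRS loading spread evenly over the panel). Per-SNP risk alleles in the
fixtures are a convention of the generator, not an empirical claim.

What the generator does **not** emulate: realistic correlation structure
among nutrients and questionnaire items, nonlinear or interaction effects,
informative (MNAR) missingness, linkage disequilibrium, or measurement
error. Passing recovery tests therefore show that the pipeline recovers
additive planted signals under benign missingness — not that it would
rank correlated real-world predictors without the instabilities the rank
CIs are designed to expose.

## Numerical choices and scaled problem sizes

- All randomness flows from one master seed through spawned child seeds;
  the first M′ imputations are unchanged when M grows, and reruns are
  byte-identical.
- The 20-seed recovery study (and the acceptance script) runs the study
  conditions n=300, p=50, M=5, B=500, K=5, GBM ≤ 500 trees with fivefold
  CV, with the imputation forests scaled to 15 trees over 2 cycles so the
  whole study completes in minutes on a single core; the imputation
  module's defaults (100 trees, cap 10) are unchanged. The
  dominant-signal rank-CI experiment uses p=20, M=10, B=200.
- The calibration line regresses predicted on observed by default
  (`calibration_direction` flips it); the direction is recorded in the run
  metadata because the two conventions are easy to confuse in
  predicted-vs-observed plots.
- The optional correlation pre-filter (drop the later column of any pair
  with |Pearson r| above a threshold, pairwise-complete) is **off** by
  default: a sensible threshold is study-specific and silently guessing
  one would change the variable set under the user's feet.
- OOB pseudo-R² uses the population variance of the outcome
  (1 − MSE_OOB/Var(y)), so mean-prediction gives exactly 0.
- Rank percentiles use linear interpolation over the M per-imputation
  ranks; a normal approximation cannot produce the degenerate (1, 1)
  interval that a consistently top-ranked variable must report.

## Limitations

- Ordinal encoding of categoricals differs from native factor splits;
  with the low-cardinality questionnaire levels used here the effect on
  rankings is small, but high-cardinality unordered factors would need a
  different encoding.
- T is a score for ranking stability, not a test statistic; no reference
  distribution or degrees-of-freedom correction is attached to it.
- The HWE chi-square is asymptotic; very rare minor alleles would warrant
  an exact test (hook present, not implemented).
- GBM relative influences carry no within-imputation standard error, so
  they pass through rank summaries and the consensus but not the pooled
  T computation — only the forest side yields standardized scores.
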