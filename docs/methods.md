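# Methods

## The wrapper classifier

Every selector is evaluated through the same model: a two-class linear
discriminant, prediction `1 iff ω·x > S`. `fit_lda` solves
Σ_pooled ω = μ₁ − μ₀ on internally standardized columns (each column
centered and scaled to unit variance; zero-variance columns are left at
scale 1 and receive weight 0). The threshold S is the standard
prior-adjusted midpoint ½ω·(μ₀+μ₁) + log(π₀/π₁), mapped back to the raw
feature scale. Consequences of the internal standardization:

- predictions are *exactly* invariant to affine rescaling of any feature
  column (the scale is absorbed into ω), and
- `feature_importance` returns |ω_j|·s_j — the standardized-space weight
  magnitude — so importance ordering does not depend on feature units.
  For models constructed directly from a weight vector (scale 1) this is
  plain |ω_j|.

Degenerate covariances never abort a fit: for d < n the solve uses a
pseudo-inverse (`pinvh`), whose minimum-norm solution splits weight
symmetrically across exactly collinear columns, so a duplicated feature
leaves predictions unchanged; for d ≥ n a Ledoit–Wolf shrinkage estimate
replaces the pooled covariance.

Balanced accuracy is (sensitivity + specificity)/2 — exactly 0.5 for any
constant predictor regardless of class balance, which is why it is the
right wrapper score for the 182/52/70 class imbalances. Cross-validation
is stratified k-fold with seeded shuffling; k defaults to 5, the smallest
common choice that keeps ≥ 10 positives per fold for the rarest task
(n = 52 positives of 252). Fold sds are population sds (divide by k), so
reports reproduce bit-for-bit. Whether published wrapper accuracies of
this kind are resubstitution or cross-validated is often ambiguous; the
harness computes CV as the headline number and resubstitution appears in
selector traces where noted.

## Selectors

**HCFR.** Feature affinity 1 − |Pearson r|, *single-linkage* clustering
cut at distance 1 − S. Single linkage is the one linkage for which the
cut provably bounds every cross-cluster pair: after cutting at t, any two
clusters have minimum inter-pair distance > t, hence every selected pair
satisfies |r| < S. One uniformly seeded representative per cluster.
Zero-variance features have undefined correlation and become singleton
clusters, flagged in the result details.

**RFE.** Refit–remove loop; the `n` least important features by |ω| are
dropped per step (default n = 1), ties broken by removing the larger
catalog index, which makes the path deterministic and nested (the p′ < p
result is a subset of the p result at n = 1). In RFE-CV, per-step
importance is the fold mean of |ω| — not |mean ω| — so sign
inconsistencies across folds cannot cancel a genuinely useful feature.
The implicit variant scans the full path to one feature and returns the
smallest count whose fold-mean BACC is within `trade_off_sd` fold-sds (at
the best step) of the best mean.

**HAFF.** At each iteration: find all pairs with r < −T among active
features (T = 0.95 by default), remove from each pair the member with the
smaller fitted |ω| (tie: larger index), refit, repeat until no such pair
remains. The rationale: an anti-correlated pair lets the discriminant
place huge opposing weights on both members, so at least one of them
looks far more important than it is; eliminating one member per pair
restores |ω| as a usable importance signal for the downstream selector.

**SDA.** Two-class sparse discriminant analysis is implemented as
penalized optimal scoring: regress the centered class indicator on
standardized features under min_β ‖y − Xβ‖² + λ‖β‖₁ + γ‖β‖₂² (solved by
coordinate descent through scikit-learn's ElasticNet with the appropriate
reparameterization; λ = 0 falls back to closed-form OLS/ridge). λ is
tuned by geometric bisection between ~0 and the null threshold
2·max_j |x_jᵀy| (above which the support is empty) until the support size
equals p. The ridge weight γ (default 0.1) stabilizes the path on
correlated blocks. The support size is non-increasing in λ only up to
occasional single-feature re-entries (the standard lasso re-entry
phenomenon at weak ridge); the bisection therefore tracks the nearest
support seen and, when the support jumps past p everywhere in the
bracket, returns the closest achievable size with an explicit
`cardinality_miss` warning in the details rather than failing. After
selection, an LDA is refit on the support for the recorded accuracy.

**GA.** Binary-mask genetic algorithm, written in-package: tournament
selection (size 3), uniform crossover (probability 0.7), per-bit flip
mutation (probability 1/d), single-individual elitism, population 60,
150 generations by default; all randomness from one seeded generator and
all fitness evaluations cached by mask. The objective (minimized) is
λ₁·c₁ + λ₂·c₂ with λ₁ = λ₂ = 1, c₂ = −(CV-mean BACC on the masked
features; −0.5 for the empty mask) and c₁ = max(|P| − p, 0). The
cardinality term is deliberately the *excess* penalty: the alternative
form min(|P| − p, 0) rewards ever-smaller sets and never penalizes
exceeding the target, which contradicts the stated purpose of capping the
feature count; it remains available as
`GAParams(penalty_form="printed_min")` for comparison. The p-limit is
soft — the winner may be smaller than p, and larger only if its penalized
fitness still wins.

**Dual phase.** Optional HAFF prefilter, then SDA or RFE down to q
(~50% of the panel), then the GA restricted to those q survivors down to
p (~10%). This turns an intractable 2¹²⁰ search into SDA/RFE screening
plus a 2⁵⁰-space GA, which is the practically efficient regime.

## Synthetic data

The generator emulates the statistical pathologies the selectors are
designed for, not the imaging physics. Features are zero-mean
multivariate normal with a target correlation matrix assembled from
equicorrelated blocks, anti-correlated pairs and independent remainder;
eigenvalue clipping with diagonal renormalization repairs indefiniteness
and raises a configuration error if any target entry moves by more
than 0.02. Labels follow a logistic model on a planted informative
subset — latent score `effect_size/√k · Σ informative + logistic noise` —
rank-thresholded so class counts are exact (182/52/70 at the study
shape). ECS scores are ranked within the pathologic-positive subset only,
so ECS ⊂ pathologic holds by construction; non-pathologic is the exact
complement of pathologic, and an inconsistent configured prevalence is a
configuration error.

Defaults and why:

- `paper_shape_config`: 252 × 120, blocks (6 @ 0.97, 4 @ 0.96), two
  anti-pairs at −0.97, 10 informative features, effect size 2.0. The
  correlation levels sit just above the T ≈ 0.95 regime the filters
  target; the effect size gives a clearly-above-chance but imperfect
  task (all-feature CV BACC ≈ 0.6 at this n/d), which is the regime where
  selector quality actually matters. The correlation spectrum of a real
  cohort is not otherwise constrained, so block sizes/levels are
  calibration choices of this package.
- `planted_config`: independent features, a small planted support with
  effect size 3.0 — strong enough that the planted features are
  unambiguously the informative ones, which is what a recovery oracle
  needs.
- Informative features occupy the trailing (independent) columns so that
  block membership and informativeness stay orthogonal concerns.

What the generator does *not* emulate: non-Gaussian marginals, scanner
and segmentation batch effects, heteroscedastic noise, label noise, and
feature-scale heterogeneity (columns are unit-variance by construction,
though the classifier standardizes internally anyway). Passing recovery
tests here therefore shows algorithmic correctness under the stated
correlation/signal model — not clinical performance on real cohorts, and
absolute BACC levels on synthetic data are not comparable to
dataset-specific published values.

## Benchmark harness

Repetition i uses seed base_seed + i for both the selector and the
scoring CV split: repetitions are independent, yet the whole report is a
pure function of (data, config) — rerunning produces bit-identical JSON.
Failed repetitions are recorded with their reason (never silently
dropped, so frequency denominators always equal R); a run aborts when
more than 20% fail. Run names follow
`<Phase1><q>[<Phase2><p>]_(HAFF|nohaff)_BACC`. The two-stage protocol
defaults to p = 51 (≈50% reduction) and p = 10 (≈10% retained), both
overridable per spec.

## Problem sizes in tests and the acceptance script

The verification suite uses desk-scale problem sizes chosen so each check
is statistically meaningful: GA-vs-enumeration at d = 12 (4096 masks,
20 fixtures, ≥ 19 must agree), single-feature RFE recovery at the full
study shape d = 120 (10 seeds), dual-phase SDA30GA3 recovery at d = 60
(20 repetitions, ≥ 15 exact recoveries), SDA cardinality at p ∈ {10, 51}
(10 seeds each), and an R = 20 harness run (scaled down from the
R = 100 protocol) for the determinism/shape/naming contract.

## Known limitations

- Only binary tasks; the three study labels are handled as three
  one-vs-rest problems, not one multi-class discriminant.
- The GA is single-objective (weighted sum); no Pareto front is produced.
- SDA's exact-cardinality tuning assumes the support path is close to
  monotone in λ; pathological designs could defeat the bisection, which
  then reports the nearest achievable support rather than searching the
  full path.
- HCFR's guarantee is about correlations only; it is label-blind and is
  expected to underperform supervised selectors at aggressive reduction.
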