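# Methods

## Estimators

All information quantities are plug-in (maximum-likelihood) estimates on
empirical cell probabilities, in bits (log base 2; any fixed base preserves
every argmax the selectors take).  `0·log 0 := 0`, and negative
floating-point residue is clamped to zero, so estimates satisfy
`0 ≤ I(X;Y) ≤ min(H(X), H(Y))` up to 1e-12.  Conditional mutual information
is the p(y)-weighted average of per-stratum MI.  No bias correction is
applied: the estimators match what compiled filter-selection libraries in
this field compute, and the greedy selectors only compare scores across
candidates at a common sample size, where the bias largely cancels —
*except* across candidates of different discretized cardinality (see
Limitations).

**Discretization.**  Counts with at most `n_bins` distinct integer values
are rank-encoded as-is; anything else is cut into `n_bins = 10`
equal-frequency bins.  Equal-frequency binning is the robust choice for OTU
tables, whose heavy zero-inflation collapses any equal-width scheme: ties at
a cut point fall into the lower bin, so a mass of zeros occupies exactly one
state.  `n_bins` is exposed on the CLI (`--bins`).

## Greedy forward selection

The search adds, for k iterations, the candidate maximizing

    J(X,Y,F) = I(X;Y) − α(|F|) Σ_{X'∈F} I(X;X') + β(|F|) Σ_{X'∈F} I(X;X'|Y)

or a criterion-specific aggregation.  The catalog: MIM (α=β=0), MIFS (α=1,
β=0), mRMR (α=1/|F|, β=0), JMI (α=β=1/|F|), CIFE (α=β=1), CMIM
(min_{X'∈F} I(X;Y|X')), ICAP (I(X;Y) − Σ max(0, I(X;X') − I(X;X'|Y))),
DISR (Σ I(X,X';Y)/H(X,X',Y)), and CondMI (I(X;Y|F) with F as one joint
variable).  The nonlinear forms follow the standard unifying-survey
definitions.  With an empty F every criterion reduces to I(X;Y).

Per-candidate redundancy sums are cached and extended by one term per
selected feature, so a k-feature selection costs O(kK) MI evaluations rather
than O(k²K); the accumulation order matches the from-scratch
`objective_score`, so the two paths agree bitwise (the test suite verifies
every step against an exhaustive scan).  Ties in the argmax go to the lowest
feature index, making selection fully deterministic.

## NPFS

Each of `n_bootstraps` replicates draws ⌈subsample_fraction·M⌉ samples with
replacement (default fraction 1.0 — ordinary bootstrap resamples), reruns
the base selector for k features, and increments the selected features'
counts.  A replicate whose draw is single-class is redrawn (up to 100
times).  Under the no-information null each feature is selected with
probability p₀ = k/K per replicate, so a feature is declared relevant when
its count strictly exceeds the smallest ζ with
`P(Binomial(n_bootstraps, p₀) > ζ) ≤ α`; strict inequality makes the
per-feature test size ≤ α by construction.  Defaults: 100 bootstraps,
α = 0.05, base objective MIM.

Replicate b is seeded with `seed + b`, so the counts are a sum of
order-insensitive independent indicators and the result is bitwise identical
for any `n_workers` (verified byte-for-byte through the CLI).

## Lasso

Exactly the least-squares form on ±1 labels — not logistic lasso:

    θ* = argmin (1/2M)‖y − Xᵀθ‖₂² + λ‖θ‖₁.

Counts are converted to per-sample relative abundances first; features are
*not* standardized by default (a `standardize` flag exists, and the
examples show when it matters).  The grid is 100 log-spaced values from
λ_max = (1/M)·max_j |X_j·y| down to 1e-4·λ_max; λ_max is the exact
subgradient threshold below which the solution leaves zero, and `fit_lasso`
returns exact zeros at and above it.  λ is chosen by 5-fold stratified,
seeded cross-validation minimizing the held-out squared error (the data-fit
term only, not the penalty), ties going to the larger (sparser) λ; the final
model is refit on all data.  The convex subproblems are solved by
scikit-learn's coordinate descent, and every returned fit is checked against
the stationarity conditions (|(1/M)X(y−Xᵀθ)|_j ≤ λ on the zero set, = λ·sign
θ_j elsewhere, tolerance 1e-6); a violating fit raises rather than returns.
Support = {j : |θ_j| > 1e-8}, reported in descending |θ_j| with the
coefficients as scores.

## Synthetic studies

The generator emulates a balanced two-class 16S-style study: per-feature
baseline abundances are lognormal weights (σ = 1.5 — a heavy-tailed
composition with a few dominant taxa) scaled to an expected per-sample depth
of 5 000 reads, and counts are negative binomial with shape r = 0.5
(variance μ + μ²/r, the overdispersion typical of OTU tables).  Planted
structure:

* *informative* — the NB mean is shifted between classes by `effect_size`
  baseline standard deviations (default 2.0, a strong biomarker);
* *redundant* — informative counts plus Poisson noise;
* *XOR pairs* — two-level presence/absence features whose joint parity
  equals the class while each member is **exactly** class-balanced (its
  empirical marginal MI is identically zero) — an idealized
  jointly-informative pair;
* *noise* — class-independent NB counts.

What it does **not** emulate: compositional closure coupling between taxa,
phylogenetic correlation structure, sequencing-depth variation between
samples, batch effects, or zero-inflation beyond what the NB produces.
Passing tests therefore demonstrate the selectors' statistical behavior
under a clean overdispersed count model, not performance on any particular
real cohort.

## Problem sizes

The test and reproduction runs use desk-scale studies — up to K = 500
features and M = 200 samples, 100 bootstraps, 10–20 seeds per Monte-Carlo
estimate — chosen so the full suite re-runs in a few minutes while keeping
every Monte-Carlo margin interpretable.

## Known limitations

**Greedy search cannot enter a pure interaction.**  Every criterion's first
step is the marginal-MI argmax, so a feature pair that is *only* jointly
informative (XOR-style) is invisible until one member is already in F.  The
conditional-redundancy reward works exactly as intended once seeded — with
one XOR member selected, JMI scores its partner a full bit above the best
noise feature — but on a table of one XOR pair plus noise, JMI ranks the
pair at the tail just as MIM does.  Detecting pure interactions from scratch
requires pairwise or exhaustive search, which is outside the greedy
contract.

**NPFS size on a fixed dataset.**  The binomial null assumes independent
replicates, but bootstraps resample the *same* dataset, so features with
high chance plug-in MI on the realized data are re-selected persistently and
the counts are overdispersed relative to Binomial(k/K).  On null data the
declared-relevant fraction is ≈ 0.16 at α = 0.05 under the default
generator (it is ≤ α when each replicate sees fresh data, as the unit suite
verifies).  The effect is amplified by cardinality heterogeneity: plug-in MI
bias grows with the discretized support size, so abundant (high-cardinality)
features are systematically favored under the null.  Treat NPFS counts as a
stability ranking and its α as nominal, not exact.

**CV-min lasso overselects.**  Minimizing held-out error is the prescribed
rule, and it is not support-consistent: with a ±1 response that no sparse
linear model fits exactly, the CV minimum sits at a small λ and admits
spurious features.  Without standardization the converse failure dominates —
rare taxa carry negligible linear signal on the relative-abundance scale and
are missed.  The support should be read as a predictive sparse model, not as
an exact recovery of the causal feature set.
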