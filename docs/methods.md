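# Methods

## Model

Each variable (OTU abundance or environmental factor) is a scalar time
series on a shared, equally spaced time grid. Causality from X₁ to X₂ is the
Granger notion: the restricted model regresses x₂(t) on its own lags
1…p, the full model adds lags of x₁, both by ordinary least squares, and

    GC(x₁→x₂) = ln( RSS_restricted / RSS_full ).

The variance in the defining log ratio is the maximum-likelihood estimate
RSS/n_eff; because both models are always fitted on the identical window
t = p+1…T, the n_eff factors cancel and the statistic is the plain RSS
ratio. Nesting guarantees GC ≥ 0; GC = 0 exactly when the cross-lag
coefficients explain nothing.

Significance of the cross-lag block (H₀: all p cross-coefficients zero) is

    F = (T − 2p − 1)/p · (RSS_r − RSS_f)/RSS_f,

referred to F(p, T − 2p − 1). The package keeps this printed-form df
convention for the bivariate test; the exact residual df of the
intercept-bearing full model on the trimmed window is T − 3p − 1, and the
difference is a ~2.5 % scale factor at the monthly-series lengths (T ≈ 44)
this method targets. Simulated null calibration (the acceptance checks)
shows the realised type-I error at α = 0.05 stays within [0.03, 0.07] and
p-values are near-uniform, so the convention is retained as stated. The
identity gc = ln(1 + f·p/(T − 2p − 1)) is enforced as an internal
consistency check on every computed pair.

The conditional statistic fits the trivariate models with and without the
source's lags, both including the mediator's lags, on the same window:
GC(Y→X|Z) = ln(RSS_reduced/RSS_full). Its F-test uses df1 = p and the exact
df2 = (T − p) − k_full, where k_full counts all coefficients of the full
model; with an empty conditioning set the statistic reduces to the
bivariate one exactly (a tested invariant at 1e-12).

## Pipeline and parameters

Steps run in this order; every threshold is a `RunConfig` key and is
recorded in the JSON-lines run log.

- **Missing data** (`min_T`, default 10): listwise deletion — any time point
  with a missing value in any variable is dropped for all variables, because
  all pairwise regressions must share one lag grid. Zeros are observations,
  never missing.
- **Abundance filter** (`mean_thresh` 1.0, `zero_frac_thresh` 0.5,
  `filter_combine` "and"): an OTU is removed when its mean is below
  threshold AND its zero fraction above threshold. The combiner is
  configurable to "or" because the filter is also meaningful distributively;
  "and" (remove only doubly-poor taxa) is the default as the more
  conservative reading. Environmental variables are exempt — the filter is
  an OTU dropout-noise control — but are screened for stationarity.
- **ADF screen** (`adf_alpha` 0.05, `adf_regression` "constant",
  `adf_max_lags` "auto_aic"): augmented Dickey–Fuller with intercept, no
  trend term (trending/seasonal variables are meant to be removed, not
  detrended away), augmentation order by AIC up to ⌊(T−1)^(1/3)⌋. A series
  failing to reject the unit root at α is removed. Constant series cannot
  reject and are flagged non-stationary with a warning. The test itself is
  statsmodels' `adfuller`; the test suite validates it against an
  independent OLS implementation of the Dickey–Fuller auxiliary regression.
- **Lag order** (`lag_selection` "bic", `p_max` min(4, T/10)): chosen per
  pair by BIC on the joint bivariate model over a common comparison window,
  ties to the smaller order; a fixed global p can be forced for
  comparability across pairs. An intercept is always included by default
  (abundances are not mean-zero); it can be disabled for the textbook
  zero-mean form.
- **FDR** (`q_threshold` 0.05, `pi0_method` "smoother"): one family of all
  n(n−1) tests — OTU–OTU, OTU–env, env–OTU and env–env pairs together,
  since a single q-threshold governs the whole scan. π₀ is estimated from
  π₀(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.95 smoothed by a natural cubic
  smoothing spline with 3 effective degrees of freedom (penalty bisected so
  the smoother matrix has trace 3) evaluated at λ = 0.95, clamped to (0, 1];
  a non-positive estimate is clamped to 1/m with a warning. With
  `pi0_method: bh` the q-values are exactly Benjamini–Hochberg. Degenerate
  pairs (perfect fits) are excluded from the family rather than given p = 0.
- **Pruning** (`mediator_policy` "two_path", `prune_rule` "ftest_alpha",
  `prune_alpha` 0.05): a single pass over the unpruned edge set. Candidate
  mediators for Y → X are variables Z with Y → Z and Z → X already in the
  graph (the configuration in which a chain can mimic the edge); a config
  option widens this to all other variables. Mediators are conditioned one
  at a time — the trivariate model — because joint conditioning on all
  variables is infeasible at T ≈ 44 with ~90 variables. An edge is kept
  only if the conditional F-test retains it against every mediator. A raw
  conditional-GC threshold rule is available for replicating published
  conditional values; the F-test rule is the default since a raw threshold
  has no calibrated size. Conditional tests are confirmatory and do not
  re-enter the FDR family. Pruning decisions are all made against the
  unpruned graph, so the pass is order-independent and idempotent.
- **Output**: edge TSV (direct + pruned with status), SIF and GraphML for
  Cytoscape, pruning audit log, run log. All writers sort edges
  lexicographically, making outputs byte-deterministic.

Cycles (including mutual causality) are permitted and reported with a
warning; acyclicity is an empirical property of some datasets, not a model
constraint. The undirected edge set Eu of the graph formalism exists in the
container but is not populated: the procedure produces directed edges only.

## Synthetic data

`simulate_var` draws from a stable VAR(p) with Gaussian innovations:
x(t) = c + Σₖ Bₖ x(t−k) + ε(t). Stationarity is checked via the companion
-matrix spectral radius; a 200-step burn-in discards transients; the state
is initialised from the innovation distribution; seeds are explicit and
mandatory. Motif constructors (`pair`, `chain`, `fork`, `collider`, `null`)
use cross-coefficient 0.6 and self-coefficient 0.3 at lag 1 — strong enough
that a T ≈ 300 series detects the planted edges with near-certainty, while
every motif stays comfortably stationary (the motifs are triangular, so the
radius equals the self-coefficient). Optional post-transforms shift series
nonnegative or Poisson-round them to mimic count data; `missing_rate`
injects missing cells to exercise the cleaning path.

What the generator does *not* emulate: compositional closure (relative
abundances summing to one), seasonality, nonlinear or state-dependent
interactions, and overdispersed zero-inflation. Passing tests therefore
demonstrate correctness of the statistics and the pruning logic under the
model's own assumptions, not robustness of Granger inference on real
compositional microbiome data.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq`; rank deficiency raises a collinearity error
  naming duplicated/constant regressors rather than silently pinv-ing.
- A full-model RSS below 1e-12 is a perfect fit: the pair is reported
  `degenerate`, excluded from FDR, never given p = 0.
- F statistics are clipped at 0 (round-off can make the RSS difference
  infinitesimally negative); GC values likewise.
- q-values use a stable sort and a reverse cumulative minimum, so tied
  p-values share one q and monotonicity holds exactly.
- BIC/AIC comparisons use a strict-improvement margin of 1e-12, so exact
  ties resolve to the smaller lag order.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
the scale the method is designed for: pair/chain/fork motifs at T = 300–500,
null calibration at the monthly-observatory length T = 44 (2000 replicates),
ADF calibration at T = 100–500 (2000 replicates), and an end-to-end
20-variable network (380 ordered-pair tests). These sizes give Monte-Carlo
standard errors well inside the asserted bands while keeping a full run in
well under a minute of compute for the suite's heavy tests.

## Known limitations

- The bivariate df convention slightly inflates the F scale (see above);
  calibration stays within the asserted band at the target lengths, but at
  very small T with large p the distortion grows.
- Granger causality is predictive, not interventional: edges are statistical
  statements conditional on the measured variable set, and latent common
  drivers outside the table cannot be excluded.
- Listwise deletion of missing time points distorts the lag structure when
  gaps are interior (the series is treated as contiguous after deletion);
  with heavy missingness an explicit gap-aware design would be preferable.
- Mediators are tested singly; a mediating *set* whose members are
  individually insufficient would not be detected under the default policy.
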