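# Methods

This note documents the models, calibration procedures, algorithmic choices,
and known limitations behind `survbench`. It is the package's account of its
own science; every number quoted here is computed by the test suite or the
acceptance script.

## Data-generating model

Observed data are right-censored triples (yᵢ, δᵢ, xᵢ) with y = min(T, C),
δ = 1(T ≤ C); ties between event and censoring times count as events.
Simulated datasets additionally retain the latent true times T, which is what
makes the absolute-loss metric computable.

### Covariates

The base design has ten independent covariates: X₁ ~ Ber(0.5),
X₂…X₆ ~ U(0,1), and X₇…X₁₀ five-level categoricals with uniform cell
probabilities (0.2 each — the multinomial probabilities are configurable,
uniform is the shipped default). Three extra-variable levels model nuisance
structure:

- **correlated**: three mean-zero normals with Pearson correlation 0.75 to
  X₂ (the designated "important" covariate, configurable). They are built on
  the normal score Φ⁻¹(X₂) with latent correlation
  0.75 / √(3/π) ≈ 0.767, because corr(Z, Φ(Z)) = √(3/π) for Z ~ N(0,1); the
  observed correlation with the uniform covariate is then exactly 0.75 in
  population, which the tests verify by simulation at n = 10⁵.
- **noise**: thirty standard normals with equicorrelation 0.5 (one shared
  factor, √0.5·Z₀ + √0.5·Zⱼ) plus twenty independent standard normals.

Extras always carry coefficient zero: they are distractors for the forests,
not part of the signal.

### Linear predictors

Four shapes of x′β exercise qualitatively different regression surfaces.
Categorical effects are dummy-coded with level 1 as reference; the shipped
default coefficient table gives every covariate a non-trivial effect with
mixed signs and non-monotone categorical patterns (values in
`dgm.default_coefficients`). Only relative sizes matter, since calibration
rescales the whole vector. The shapes:

- **baseline** — first-order terms in all ten covariates;
- **poly_int** — the X₂…X₅ linear terms replaced by X₂², X₃X₄, X₅², X₂X₅,
  plus an added X₃X₆ interaction (interactions involve numeric covariates
  only);
- **sine** — the X₂ term replaced by sin(2πX₂), mimicking seasonality;
- **piecewise** — X₂ and X₃ made continuous piecewise-linear with knots at
  1/3 and 2/3 and a separate slope per segment (defaults ±3 alternating,
  chosen so each segment contributes roughly a unit swing). Continuity at
  the knots is structural (segments are parameterized by slope, not
  intercept) and tested by evaluating both segment formulas at the knots.

These concrete forms and coefficients are package defaults, exposed for
override through `LinearPredictorSpec.coefficients`.

### Response families

All draws use the inverse cdf at U(0,1) variates (u is used directly in
−log u; distributionally identical to 1−u, fixed for reproducibility):

- **Weibull PH** (shape ρ = 2, scale λ = 1 by default):
  t = (−log u / (λ e^{x′β}))^{1/ρ}.
- **Lognormal AFT** (intercept 0, σ = 0.5): t = exp(β₀ + x′β + σΦ⁻¹(u)).
- **Generalized gamma** (a = 1, b = 2): t = a e^{x′β} · Q_Γ(u; k)^{1/b},
  where Q_Γ(·; k) is the gamma quantile function. The shape k is 1 where
  X₁ = 0 and 1/16 where X₁ = 1 (the assignment of halves is a package
  choice). k = 1 reduces exactly to Weibull(a e^{x′β}, b), verified by a
  KS test; k = 1/16 with b = 2 has bk < 1, giving an infinite-at-zero,
  decreasing-then-increasing (bathtub) hazard.

**Conditional vs marginal crossing.** The bathtub construction makes the
*conditional* hazards and survival curves of the two X₁ halves cross. The
test suite verifies crossing and the bathtub/monotone hazard contrast on the
isolated construction (all coefficients zero except X₁). Marginally — under
the full calibrated linear predictor — the heavy lognormal-type spread of
e^{x′β} mixes scales so strongly that the k = 1/16 subgroup's survival stays
below the k = 1 subgroup's everywhere; this is a property of the model, not
a defect, and is why the crossing test conditions on the construction.

### Censoring

Censoring times are i.i.d. exponential, independent of everything else; no
informative censoring and no covariate missingness are modelled.

## Calibration

Changing the response family or predictor shape changes how much of the
marginal variance of T the covariates explain, confounding method
comparisons. Both are therefore calibrated per cell:

1. **Signal.** Pseudo-R² = Var(E(T|X)) / (Var(E(T|X)) + E(Var(T|X))),
   estimated by Monte Carlo over covariate draws (default 10⁵) with
   closed-form conditional moments: E(T^m|x) is Γ(1+m/ρ)·θ^{−m/ρ} for the
   Weibull, lognormal moments for the AFT, and a′^m Γ(k+m/b)/Γ(k) for the
   generalized gamma. A single multiplier (`signal_scale`) on the whole
   coefficient vector is root-solved (Brent) so SNR = R²/(1−R²) hits the
   target; the default target is R² = 0.5 (SNR 1), chosen as a "relatively
   high" signal level and applied identically to every cell. Coupling scale
   and regression parameters through one multiplier is a deliberate
   simplification.
   The SNR profile in the multiplier is increasing for the Weibull and AFT
   families but hump-shaped for the generalized gamma (the k-switch on X₁
   injects signal even at zero scale: R² ≈ 0.54 at 0, saturating near 0.17
   as the scale grows). The solver therefore demands a *unique* crossing of
   the target on its log-spaced scan grid and raises a diagnostic error when
   the target is unattainable or ambiguous. The scan stops at scales whose
   moments overflow double precision; those are unattainable anyway.
2. **Censoring rate.** With the calibrated signal fixed, the exponential
   rate is found by bisection (in log-rate space, ≤ 60 steps, tolerance
   0.005 by default; the validation tests use 0.001). The censoring
   proportion at a candidate rate is the Monte-Carlo mean of 1(C < T) using
   common random numbers (cᵢ = −log uᵢ / rate with u fixed), which makes the
   empirical proportion exactly monotone in the rate.

Calibration records are cached per (family, predictor shape) — extras have
zero coefficients and censoring does not touch latent times — and per
censoring level for the rate.

## Forest engine

All methods share one recursive tree grower over candidate covariates
(M = ⌈√p⌉ sampled per node by default) and differ in resampling, split
scoring, and aggregation. Defaults: 500 trees (experiments use 100),
min_node = 6 (minimum child size), min_events = 1 (every terminal node keeps
at least one unique event time — enforced structurally and tested). Split
scores are evaluated simultaneously at all cutpoints of a candidate via
prefix cumulative sums; the log-rank numerator at a cut equals the prefix sum
of the log-rank scores aᵢ = δᵢ − Ĥ_NA(yᵢ), so only the hypergeometric
variance needs a two-dimensional pass.

- **RSF family** (bootstrap + Nelson–Aalen terminal nodes, ensemble
  S = exp(−H̄)): log-rank (absolute standardized statistic); log-rank score
  (rank-score standardization — the statistic is the centered prefix sum of
  the aᵢ scores with its sampling-without-replacement variance); C-index
  (concordance of the binary left/right membership as predictor, computed for
  all cutpoints through pairwise contribution matrices and 2-D prefix sums;
  orientation-free via max(C, 1−C)); Brier (negative summed children Brier
  scores at their own KM curves, integrated exactly over the node's observed
  times); L1 (exact step integration of |Ŝ_L − Ŝ_R| over the children's
  union event grid — the open design choice of integration domain resolved
  to the union grid).
- **Categorical splits** order levels by within-level KM median and treat
  the ranks as ordinal, avoiding 2^{L−1} subset enumeration; unseen levels at
  prediction time route to the majority child recorded at the split.
- **Tie-breaks**: strictly greater score wins; candidates are scanned in
  ascending covariate index and cutpoints in ascending order, so equal scores
  resolve to the smallest feature index, then smallest cutpoint.
- **RIST**: extremely randomized trees (one uniform random cutpoint per
  candidate, best by log-rank) on the full sample, no bootstrap. Censored
  rows are then imputed from their ensemble conditional survival distribution
  truncated to (cᵢ, ∞) by inverse-cdf sampling on the step function — tail
  mass beyond the grid maps to the last grid time, floored just above cᵢ so
  imputed times always exceed the censoring time (truncation itself is a
  package choice: imputing below cᵢ would contradict the observed data).
  Imputation and refit repeat k ≥ 1 times (k = 1 default, the configuration
  the comprehensive comparisons retain); each round reuses the same tree
  seed substreams, so on uncensored data the refit replays the initial
  ensemble exactly. One imputed dataset is drawn per round and shared by all
  trees of the refit.
- **RotSF**: per tree, bootstrap; one-hot encode categoricals; partition the
  encoded columns at random into subsets of size 3 (default); rotate each
  subset by the eigenvectors of its bootstrap covariance (identity fallback
  for constant columns); grow a log-rank tree on the rotated features.
  Rotation blocks keep their column positions, so size-1 subsets reduce to
  sign flips and reproduce the plain log-rank forest — a tested equivalence.
- **CIF**: subsampling without replacement (0.632·n); at each node the
  association of every candidate with the survival outcome is tested by the
  standardized linear statistic Σaᵢg(xᵢ) with log-rank scores (asymptotic
  normal reference by default; exact permutation behind
  `cif_permutations`), Bonferroni-corrected over candidates; the node stops
  when the minimum adjusted p-value exceeds α = 0.05. Under a pure-noise
  null the root stops in ≈95 % of trees (the Bonferroni correction makes the
  test mildly conservative, measured ≈96–97 %). Predictions use
  nearest-neighbour weights — each training row weighted by the fraction of
  trees in which it shares the query's terminal node, normalized per query —
  feeding a weighted Kaplan–Meier.

Determinism: all randomness derives from `ForestSpec.seed` via SeedSequence
spawning with separate per-tree substreams for bootstrap, rotation, and
growth; refits replay byte-identically, and the experiment runner derives
per-replicate data seeds as a pure function of (master seed, cell,
replicate) so results are scheduling-independent.

## Error metrics

- **Absolute loss** L = (1/n)Σ|tᵢ − m̂ᵢ| against the latent true times, with
  m̂ᵢ the smallest grid time where Ŝ ≤ 0.5; when the curve never reaches 0.5
  the largest available quantile's time is used instead.
- **Concordance error** E = 1 − C by exact pairwise enumeration: pairs whose
  shorter observed time is censored (or tied and both censored) are omitted;
  unequal times score 1 when the shorter time has the shorter prediction and
  0.5 on prediction ties; equal observed times score 1 on prediction ties,
  0.5 otherwise. With no permissible pairs E is NaN — an explicit sentinel,
  never silently zero (it cannot arise at the study's test size of 200).
- **IBS** uses the raw survival-status indicator 1(yᵢ > t) with horizon
  w = max yⱼ and exact integration over the merged step breakpoints — no
  quadrature error (tested against an independent breakpoint-refined
  midpoint quadrature to 10⁻⁶). An inverse-probability-of-censoring-weighted
  (Graf-style) variant exists behind `ipcw=True` but is OFF for benchmark
  reporting: the unweighted indicator is the benchmark's printed definition,
  and the optional IPCW mode is a labelled divergence for users who want the
  conventional estimator. The L1-split forest is excluded from IBS
  summaries at the reporting layer (its original formulation yields coarse
  curve output that makes IBS incomparable).
- Exports add the variance-stabilizing transforms log(IBS) and
  log(log(L)) for downstream mixed-model analysis; rows with L ≤ 1, where
  the double log is undefined, are flagged in a dedicated column rather than
  dropped.

## Experiment design

The full factorial crosses 3 families × 4 predictor shapes × 3 censoring
levels × 2 training sizes × 3 extra levels = 216 cells; the comprehensive
design drops the 25 % censoring level (144 cells) and, at 10 replicates per
cell, yields 1440 dataset slots. Test sets have n* = 200 with latent times
retained. All methods within a replicate see identical train/test data; a
failing method is recorded with its error message and the run continues.
Relative summaries center each method's replicate-mean error on the
across-method mean within each cell (negative = better). The pilot
fractional design (60 cells) is not reconstructed — its resolution-preserving
subset is not specified in available sources — so only the full and
comprehensive grids ship.

## Problem sizes used in checks

The validation suite uses sample sizes chosen to make Monte-Carlo error
negligible relative to the asserted tolerances: 10⁵–10⁶ draws for moment and
correlation checks, 10⁵ for calibration and distributional (KS) checks, 500
replicates of n = 200 for the permutation boundary of E, and 30 replicates
with 100-tree forests for the directional ranking check at light censoring
(one-sided t-tests at α = 0.05). The covariate-free KM-floor sanity check
runs at n = 1500 with 8-tree ensembles — accuracy there is well past the
floor, so small ensembles suffice.

## Known limitations

- The oblique (penalized-Cox) forest and the censored quantile/generalized
  random-forest variants are out of scope, as are variable importance and
  honest variance estimation.
- Calibration adjusts one global multiplier, not individual scale and
  regression parameters; cells with structurally different attainable R²
  ranges (notably the generalized gamma) land on the target by trading
  coefficient magnitude against the k-switch signal.
- The synthetic generators emulate clean factorial conditions: independent
  covariates (except the designed extras), exponential non-informative
  censoring, no missingness, no time-varying effects. Passing benchmarks
  here says nothing about covariate-dependent censoring or real-world
  measurement artifacts.
- CIF's categorical association uses the same KM-median ordinal scoring as
  its splits — a simplification of the multivariate quadratic-form statistic
  used by the original conditional-inference framework.
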