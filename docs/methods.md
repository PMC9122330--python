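# Methods

`cgfdist` estimates entire distributions of child anthropometric z-scores
(height-for-age HAZ, weight-for-height WHZ, weight-for-age WAZ) per location,
year, age group and sex, and derives multi-severity prevalences — overall
(< −2 SD), severe (< −3 SD) and extreme (< −4 SD) — with draw-level
uncertainty. This note records the model, its assumptions, the tunable
parameters, and the design choices made where the design was genuinely open.

## Ensemble z-score distributions

The characteristic shape of a z-score distribution is a convex mixture of
ten parametric families: normal, log-normal, log-logistic, exponential,
gamma, mirrored gamma, inverse gamma, Gumbel, mirrored Gumbel and Weibull.
Every component is parameterized by the *same* mean μ and variance σ² via
the method of moments, so the whole mixture is a two-parameter family once
the weights are fixed.

Conventions (the literature leaves them open; these are ours):

- **Shift.** Positive-support families are fit to `x = z + shift`, with a
  single global `shift = 10` so that any plausible z-score (≥ −10) maps to
  positive support. Their moment equations use the shifted mean μ + 10.
- **Mirror.** Mirrored families are fit to `x = anchor − z` with
  `anchor = +10`; mirrored moments are (anchor − μ, σ²). The mirrored CDF
  below a threshold t is the survival function of the base family at
  anchor − t.
- **Exponential.** One parameter, so it is moment-matched on the shifted
  mean only; its variance mismatch is accepted and the weight optimizer is
  free to downweight it.
- **Infeasibility.** A family whose moment equations cannot be solved for
  the given (μ, σ²) (e.g. μ + shift ≤ 0) contributes zero density and the
  remaining weights are renormalized at that point; only if every component
  is infeasible does evaluation fail.
- **Closed-form CDFs.** The mixture CDF is the weighted sum of closed-form
  family CDFs; threshold prevalences never require quadrature.

Two shape solves have no closed form and are inverted numerically once:
for the log-logistic, with c = π/shape, the squared coefficient of
variation satisfies CV² = tan(c)/c − 1 (monotone in c); for the Weibull,
CV² = Γ(1+2/k)/Γ(1+1/k)² − 1 (monotone in k). Both inverses are tabulated
on a dense log-CV grid (4097 points over CV ∈ [1e−5, 1e3]) at first use and
interpolated thereafter, making CDF evaluation fast on large draw arrays;
interpolation error in the shape parameter is ~1e−7 relative, far below
every tolerance used downstream.

### Weight fitting

Global mixture weights (one set per indicator) are fit to microdata
sources. Per source the empirical mean, variance (n−1 normalization) and
empirical prevalences below −1, −2 and −3 SD are computed; the objective is
the unweighted sum over sources of squared differences between predicted
and empirical prevalences at the three thresholds (equal threshold
weights). The objective is minimized over the weight simplex (weights
parameterized as normalized absolute values) by Nelder-Mead restarted from
100 Dirichlet(1) initial weight sets by default; the best restart wins.
Because the per-source family CDFs do not depend on the weights, they are
precomputed once as a (sources × families × thresholds) tensor and each
objective evaluation is a tensor contraction, so restarts are cheap.

Identifiability caveat: at shift 10 the shifted positive-support families
are all nearly Gaussian for child-z-score moments (CV ≈ 0.1), so weights
between them are weakly identified; the *fitted curve* is insensitive to
this, which is why the pipeline's accuracy does not depend on recovering
the generating weights exactly.

## Spatiotemporal Gaussian process regression (ST-GPR)

Three stages per indicator (mean z-score in identity space; prevalences
below −2 and −3 SD in logit space, with delta-method observation
variances):

1. **Covariate-ensemble prior.** All covariate subsets up to size 3
   (configurable) are fit as linear mixed models with nested random
   intercepts at super-region, region and location level (statsmodels
   MixedLM, REML; OLS fallback if the mixed fit is singular). Candidates
   with a coefficient that is not Wald-significant at P < 0.05 or not in
   the a-priori expected direction are dropped. Survivors are scored by
   holdout RMSE (a random 20% of observations withheld) and blended with
   weights ∝ exp(−RMSE / min RMSE). If every candidate is dropped the
   intercept-plus-random-effects model is used (logged).
2. **Spatiotemporal smoothing.** The stage-2 estimate at a cell is the
   prior plus a weighted average of observed residuals, the weight being a
   product of a space weight (1 same country, ζ same region, ζ² same super
   region, 0 otherwise), a tricube-style time weight
   (1 − (|Δt|/(1+maxΔt))^λ)³ and an age-rank weight Ω^(−|Δa|); opposite-sex
   residuals carry zero weight. ζ, λ, Ω are selected on a small grid by
   holdout RMSE of the stage-2 surface, ties broken toward smoother fits
   (larger λ, then larger ζ).
3. **Gaussian process.** Per (location, age, sex) time series, a GP with
   mean function equal to the stage-2 surface, Matérn-5/2 kernel in year,
   and observation noise equal to the (modeling-space) data variance.
   Kernel defaults: length scale 3 years — short, because survey evidence
   arrives every few years and the stage-2 error decorrelates quickly —
   and amplitude 1.5 × 1.4826 × MAD of the data-minus-stage-2 residuals.
   The 1.5 inflation exists because the stage-2 smoother has already
   shrunk precisely the residuals the MAD is computed from, so the raw MAD
   understates the surface uncertainty away from data; with the inflation
   the 95% intervals cover the truth at 95–99% in the calibration study
   below. Cholesky failures escalate through a jitter ladder
   (1e−12 → 1e−6). 1000 posterior draws by default; summaries are the
   draw mean with 2.5th/97.5th percentiles.

## Variance recovery and severity integration

Per cell and draw, the ensemble SD is the minimizer over [0.05, 5] z-score
units of the equally weighted squared error between the ensemble
prevalences below −2/−3 SD and the ST-GPR draws of those prevalences, with
the mean anchored at the ST-GPR mean draw. Draw alignment across the three
ST-GPR models is by draw index. When the −3 target sits at the numerical
floor (≤ 1e−6), the SD is fit to the −2 target alone to avoid degeneracy.

The scalar solver is Nelder-Mead with restarts at SD ∈ {0.5, 1, 2}. The
draw-matrix solver used by `integrate_surface` is a vectorized equivalent —
a 33-point log-spaced scan of the bracket followed by golden-section
refinement, all evaluated array-wise through the closed-form mixture CDF —
chosen because hundreds of thousands of independent simplex calls would
dominate pipeline runtime; the two agree to well under 1e−3 in SD and are
cross-checked in the test suite. The recovered curve is then evaluated at
all four thresholds (−1, −2, −3, −4), so the severity ordering
extreme ≤ severe ≤ overall holds by CDF monotonicity on every draw.

## Change metrics

Relative change versus a reference year is computed at the draw level from
age-sex-specific prevalence draws: per cell-draw the ratio current/reference
is formed, and the change values 1 − ratio (positive = improvement) are
aggregated to both-sex under-5 per location with population weights.
Cell-draws with reference prevalence below 1e−9 are dropped and counted.
Summaries report the **median** with a 95% interval: near-zero reference
draws make ratio distributions heavily skewed, and the median represents
the commonly estimated values where the mean does not.

The annual-change analysis covers 1991–2019 (no 1989 reference exists for
1990; the final year is excluded as its health-system series is less
certain), labels each location-year by the sign of the UHC-index change
versus the prior year (exact ties |Δ| < 1e−9 are excluded, since only
increase/decrease groups are defined), and keeps only location-years with
severity prevalence above one per million and under-5 population above
300 000. Distributions of annual change between the improved and worsened
groups are compared with the two-sample Kolmogorov-Smirnov statistic
(supremum ECDF difference; asymptotic p-value via scipy).

## UHC transition splines

Expected prevalence against the UHC index (0–100) is modeled in logit space
as a weighted ensemble of 20 quadratic-spline submodels, each with four
random interior knots (uniform over the [0.05, 0.95] UHC quantile range,
minimum spacing 5 index points) giving five segments. Each submodel is fit
by constrained least squares with hard non-increasing constraints: the
derivative of a quadratic spline is piecewise linear, so non-positivity at
the knots is necessary *and sufficient* for global monotonicity, which
makes the constraint exactly testable. If the QP solver returns a
marginally infeasible point, a linear term equal to the residual positive
slope is subtracted (a linear function lies inside the spline space),
guaranteeing feasibility. Submodel weights ∝ exp(−RMSE) from 5-fold
location-grouped cross-validation. After a first ensemble fit, the lowest
and highest 0.5% of points by signed residual are trimmed (⌈0.005·n⌉ per
tail) and the ensemble refit once. An optional linear SDI covariate enters
additively in logit space, leaving UHC-monotonicity intact at every SDI
level.

Age-sex-specific ensembles are aggregated at each UHC grid point as the
population-weighted mean of natural-space predictions. To compare decline
trajectories across severities, each severity curve is multiplied by
reference(UHC_min)/severity(UHC_min) so all curves coincide at the lowest
observed UHC value.

## Synthetic worlds

The synthetic-data module generates every input the pipeline consumes, with
known truth:

- a complete three-level location tree under a global root;
- truth surfaces with linear-plus-random-walk trends on the mean z-score
  and on log SD, nested zero-mean offsets at the three hierarchy levels,
  and age/sex offsets. Defaults emulate a high-burden stunting setting:
  mean drifting −1.88 → −1.65 over 1990–2020 with the spread narrowing
  1.15 → 1.00, offsets of 0.15/0.10/0.08 z (mean) and 0.04/0.03/0.03
  (log SD) at super-region/region/country level, random-walk steps of
  0.01 z/yr, and a truth ensemble of 0.6 normal / 0.25 Weibull /
  0.15 Gumbel so the fitted mixture has non-Gaussian structure to find;
- microdata as i.i.d. ensemble draws per cell; tabulated reports as a
  single trinomial draw over {below −3, between, above −2}, which makes
  prev3 ≤ prev2 hold by construction;
- covariates as monotone transforms of the truth mean plus noise (plus a
  pure-noise column for the selection step to drop), UHC and SDI as
  noisy monotone maps of the country-year mean onto [0, 100], and
  populations with a fixed under-5 age composition and even sex split;
- an age-sex splitter for both-sex under-5 aggregated reports:
  proportional to the pattern's prevalence ratios and rescaled so the
  population-weighted mean reproduces the aggregate exactly.

What the generator does *not* emulate: survey design effects (clustering,
weights), measurement error in anthropometry, non-representative sampling,
missing-data mechanisms, or covariate measurement lag. Passing tests
therefore demonstrate internal consistency and statistical correctness of
the estimator under its own assumptions, not robustness to the
messiness of real survey systems.

## Study sizes and numerical tolerances

The validation studies use deliberately desk-scale worlds: the end-to-end
truth-recovery study runs 10 countries × 31 years × 2 age groups × 2 sexes
at 100 draws, with a survey in every country-year (microdata n = 4000 per
cell alternating with tabulated n = 10000) — the dense, low-noise regime in
which the chain should recover the truth; it attains a mean absolute error
of ~0.8 percentage points (overall), ~0.6 (severe) and ~0.3 (extreme).
The GP calibration study uses 200 independent location series over 31
years, observation noise SD 0.05 and stage-2 bias SD 0.04, and attains
~98% empirical coverage of the 95% intervals. The mixture-CDF oracle uses
10⁷ Monte-Carlo draws (agreement within 3 binomial SEs). Determinism is
end-to-end: every stochastic step takes an explicit seed, and pipeline
reruns are byte-identical (SHA-256 digests in the run manifest).

## Known limitations

- Stage-1 prediction uses estimated random effects for locations present
  in the data and falls back to the fixed-effects surface elsewhere; no
  national→subnational raking exists.
- The three indicators are modeled independently; coherence (e.g.
  prev3 ≤ prev2) is restored only at integration, not in the GP draws
  themselves.
- The spline ensemble implements the monotone-quadratic-spline,
  trimming and predictive-validity-weighting subset of full Bayesian
  meta-regression; priors other than monotonicity, Student-t likelihoods
  and location random effects are out of scope.
- The exponential component's variance mismatch means mixtures with large
  exponential weight have heavy right tails on the shifted scale; the
  weight optimizer handles this, but a user forcing exponential weight
  should expect it.
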