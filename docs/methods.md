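# Methods

## Model

Single-cell resistances within a clonal population are modelled as
lognormal: `log10 R ~ N(μ, σ)`, with `IC50 = 10^μ` (mM) and
heteroresistance `σ` (dimensionless, log10(mM) scale).  The lognormal
choice makes all derived concentrations positive and makes the model
equivariant under rescaling of the concentration axis: multiplying all
concentrations by *k* shifts μ by log10 *k* and leaves σ unchanged (a
property the test suite asserts).  A plain-normal variant
(`scale="linear"` in `InoculumEffectModel`) is retained for comparison;
there μ and σ are in mM.

All logarithms are base 10.  This is forced by internal consistency of the
bundled panel table: for each strain,
`10^(log10 IC50 + 3.7190·σ)` reproduces the tabulated MIC_MODEL to within
3% for all 29 strains (the acceptance script recomputes this), whereas a
natural-log reading does not come close.

Three closed forms drive everything:

* expected-maximum quantile (Blom): `z(n) = Φ⁻¹((n − π/8)/(n − π/4 + 1))`,
  so `E[max of n draws] ≈ μ + σ·z(n)`. `z(1) = 0` exactly; `z(10⁴) ≈ 3.843`.
  Accuracy is verified against Monte-Carlo means of sampled maxima (within
  5% for n = 10…10⁴).
* predicted MIC of an *n*-cell inoculum: `10^(μ + σ·z(n))`.
* MIC_MODEL: the 99.99th percentile, `10^(μ + σ·Φ⁻¹(0.9999))`,
  multiplier 3.7190.  Note `z(10⁴) > Φ⁻¹(0.9999)`, so the *expected
  measured* MIC of 10⁴ cells slightly exceeds MIC_MODEL whenever σ > 0.
  MIC_MODEL is deliberately defined by the plain percentile, not by the
  order-statistic quantile, matching its conventional definition.

Degenerate populations (σ = 0) are legal throughout: the survival curve
becomes a step function (value ½ exactly at the IC50) and the inoculum
effect vanishes.

## Estimators

**Inoculum-effect fit.** Observed `(n_i, MIC_i)` pairs give the regression
`log10 MIC_i = μ + σ·z(n_i) + ε_i`, linear in (μ, σ).  Instead of an
iterative nonlinear optimiser we solve the constrained (σ ≥ 0) ordinary
least squares exactly: the optimum is the unconstrained OLS solution when
its slope is non-negative, else the boundary solution (σ = 0,
μ = mean log10 MIC), flagged `sigma_clamped`.  This removes initialisation
sensitivity while reaching the identical optimum; the test suite verifies
the objective never exceeds a 200×200 grid search by more than 1e-8.
Residuals are taken on log10 MIC (consistent with the lognormal model);
the linear-normal variant fits raw mM.  At least two distinct inoculum
sizes are required.

**Dose-response fit.** Percent survival is fitted to
`100·(1 − Φ((log10 c − μ)/σ))` by bounded nonlinear least squares
(trust-region reflective; σ ≥ 1e-9).  Start values: μ₀ = log10 of the
concentration with survival nearest 50%, σ₀ = 0.05, with up to five
deterministic jittered restarts on non-convergence.  Zero-concentration
rows are normalisation controls, excluded from residuals.  Data must span
both sides of 50% survival; all-surviving or all-dead sets are rejected as
under-determined.  On noise-free model data the fit is a projection
(parameters recovered to < 1e-6).

**Aggregation.** The default pipeline fits each biological replicate
separately and reports the arithmetic mean ± SEM (sample SD/√k) per
parameter.  MIC_MODEL is averaged over per-replicate values — not
recomputed from the mean μ and σ — because the percentile is a nonlinear
function of the parameters.  A single fit reports SEM 0 with
`sem_defined=False`.

**Bootstrap.** Case resampling (rows with replacement within the dataset),
refitting each resample; 95% intervals are the 2.5/97.5 percentiles, plus
a pointwise 95% envelope of predicted curves.  Case resampling was chosen
over residual resampling because count-derived survival data and
grid-quantised MIC readings are heteroscedastic.  Resamples that fail to
fit (e.g. all rows from one inoculum) are dropped and counted; > 20%
failures raises an error.  Everything is deterministic given the seed.
The natural dataset unit is one biological replicate (the same unit the
fitter consumes); the coverage study below uses it.

## Simulator

The simulator emulates the two assays the estimators consume.

*Inoculum-effect assay* (`simulate_mic_exp`): for each biological
replicate × inoculum size, every concentration on an arithmetic grid
(default 0.125 mM steps up to 20 mM) × technical replicate (default 4) is
an independent well with fresh cells, as on a real microplate.  Actual
cells per well are Poisson around the nominal inoculum (default on;
switchable off for exact tests).  A well grows iff at least one cell's
resistance strictly exceeds the concentration; the population maximum is
drawn exactly via the inverse CDF of the max order statistic
(`Φ⁻¹(U^{1/n})`), so a 10⁵-cell well costs one draw.  MIC_EXP is the
lowest grid concentration meeting the scoring rule:

* `any-clear` (default): ≥ 1 of the technical wells clear — the literal
  plate-reading rule of the motivating protocol;
* `all-clear`: all technical wells clear — the conventional MIC reading.

Grid-exhausted readings are returned flagged `censored` and excluded from
fits (never imputed).

*Dose-response assay* (`simulate_dose_response`): CFU at concentration c is
Binomial(cells plated, survival fraction); percent survival is normalised
to the zero-concentration control plate.  Two default inocula (10⁴ and 10²
cells) resolve the deep tail and the upper range respectively.

**What the simulator does not emulate:** growth kinetics and
time-to-detection (growth is a binary endpoint), sorbic acid metabolism,
cell-density/quorum effects, agar-versus-broth differences, and
correlation between technical replicates (shared medium batches);
replicates are independent.  Passing recovery tests therefore demonstrate
estimator correctness under the stated sampling model, not robustness to
those real-data features.

**Scoring-rule bias.** The two scoring rules bracket the truth and neither
is unbiased at the default design.  Under `all-clear` with four technical
wells, "all wells clear" is essentially "the maximum over ≈ 4n cells is
below c", so measured MICs track μ + σ·z(4n) rather than μ + σ·z(n);
fitting with nominal n then reads the median high (the 100-run recovery
study in the acceptance script computes the size of this effect at the
default design: mean recovered IC50 ≈ 4.3 mM for a true 4.0 mM, with the
spread recovered within ~6%).  Under `any-clear` the bias runs the other
way (median low, spread high), because a single lucky clear well among
four ends the scan early.  Refining the grid shrinks both biases under
`all-clear` (asserted by a property test at 0.25/0.125/0.0625 mM); under
`any-clear` refinement *amplifies* the early-stop effect — more grid
points mean more chances of a lucky clear well — which is a good reason to
prefer `all-clear` scoring when the goal is parameter estimation rather
than protocol emulation.

## Study sizes and numerical choices

* Recovery study: 100 simulated assays at the default design (all-clear),
  truth μ = log10 4.0, σ = 0.07; coverage study: 200 single-replicate
  assays, B = 500 bootstrap resamples.  These sizes give Monte-Carlo
  standard errors of ~0.2% on the recovered IC50 mean and ~2% on coverage,
  small enough to characterise the estimators while keeping a full run
  around a minute.
* Monte-Carlo order-statistic checks use 10⁵ replicates (chunked to bound
  memory at n = 10⁴ draws per replicate).
* Strict inequality defines growth at a tie (cell resistance exactly equal
  to the well concentration does not grow); ties have probability zero
  under the continuous model and only matter for σ = 0 test fixtures.
* Dose-response fits use `scipy.optimize.least_squares` with
  xtol = ftol = gtol = 1e-14 so that projection tests are meaningful at
  1e-6.
* Percentile intervals use the empirical 2.5/97.5 quantiles with no bias
  correction (BCa was judged unnecessary at the achieved coverage).

## Panel statistics

Correlations between per-strain heteroresistance, IC50 and MIC_MODEL are
computed on the untransformed tabulated values (the quantities as plotted
in panel scatter analyses); p-values come from the exact t transform
`t = r·√((n−2)/(1−r²))`.  One-tailed p-values are half the two-tailed
value in the observed direction.  Welch's unequal-variance t-test compares
species groups with Welch–Satterthwaite degrees of freedom.  Dispersion
comparisons of IC50 use log10(IC50) — the scale on which strain-to-strain
variation is multiplicative — while heteroresistance SDs are taken on the
raw tabulated values.  Sample SDs use the n−1 denominator throughout.  No
multiple-testing correction is applied.  Species subgroups below n = 3 are
skipped for correlations with a notice; degenerate (constant) inputs are
reported as such rather than raising inside a report.

## Known limitations

* Blom's approximation is an approximation to E[max]; its error (≲ 0.3%
  over n = 10…10⁴, per the Monte-Carlo tests) is negligible relative to
  assay noise but is inherited by every fit.
* The inoculum-effect method estimates *relative* heteroresistance well;
  absolute parameter readings carry the scoring-rule biases quantified
  above and should be compared within a consistent protocol.
* The estimators assume independent errors across inoculum sizes within a
  replicate; plate-position or batch effects are not modelled.
* No mixed-effects pooling across strains and no Hill-slope dose-response
  variant are provided; the probit-style CDF is the only dose-response
  family.
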