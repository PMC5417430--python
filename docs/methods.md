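# Methods

## The model

The response is a fraction y ∈ [0, 1] (bleached or dead share of coral at
a surveyed site, the average of an area-based and a colony-based
measurement). The core estimator is the fractional logit: a conditional-
mean model

E[y | x] = G(β₀ + Σⱼ βⱼ xⱼ + Σₖ βₖ dₖ),  G(η) = 1/(1+e^(−η)),

where the xⱼ are stressor covariates (accumulated thermal and radiative
stress, wind, population density, distance from shore, depth and
depth × stressor products) and the dₖ are ecoregion indicators absorbing
time-invariant spatial differences. Coefficients maximise the Bernoulli
quasi-log-likelihood Q(β) = Σᵢ [yᵢ log Gᵢ + (1−yᵢ) log(1−Gᵢ)], which is a
valid estimating equation for the mean regardless of the true conditional
distribution — in particular with point masses at 0 or 1, which dominate
mortality data. Only the mean is modelled; no distributional assumption on
y beyond boundedness is used, which is why all inference is sandwich-based.

Two comparators are implemented from their objectives: a two-limit Tobit
(latent y* = x'β + ε, ε ~ N(0, σ²), observed y = clamp(y*, 0, 1); interior
observations contribute a normal density, limit observations the
corresponding tail mass) and OLS. With no observation at a limit the Tobit
likelihood is the normal regression likelihood and its MLE reproduces OLS
exactly; with limits at ±∞ it is OLS by construction. OLS predictions can
leave [0, 1] — the package flags this rather than hiding it, since it is
the standard argument against the linear comparator.

### Estimation and numerics

* Fractional logit: Newton/IRLS with the analytic score X'(y−μ) and
  Hessian X'WX, W = μ(1−μ) (observed = expected for the canonical link).
  Start values come from OLS on the logit of y winsorised to [0.01, 0.99].
  A halving line search guards the rare non-concave step; comparisons of
  the quasi-likelihood use a tolerance relative to |Q| because absolute
  differences below ~10⁻¹³|Q| are float noise. Convergence: max |score|
  < 10⁻⁸ (or a collapsed step with score numerically zero, < 10⁻⁶);
  200 iterations maximum, non-convergence is flagged on the result, and a
  rank-deficient design raises an error naming the collinear columns.
* Tobit: BFGS on (β, log σ) with the analytic gradient (log σ keeps the
  scale positive without bounds), followed by up to ten Newton polish steps
  on a finite-difference Hessian — BFGS line searches stall around 10⁻⁴
  from the optimum when censoring is heavy and σ is small. All-censored
  samples raise an identification error.
* Robust covariance: sandwich A⁻¹BA⁻¹ with A the (expected) Hessian and B
  the outer product of per-observation scores, scaled by n/(n−p) (HC1-
  style); the exact flavour is a convention choice, and a clustered-by-
  region variant is available as an option. For the Tobit the sandwich is
  computed on (β, log σ) and the σ SE mapped back by the delta method.

### Marginal effects

Average marginal effects are reported in outcome percentage points per
covariate unit: AME(v) = (100/n) Σᵢ gᵢ·(β_v + Σ β_{v×w} wᵢ) with
g = G(1−G), i.e. the chain rule runs through every interaction v enters;
interaction columns themselves get no AME row (their contribution lives in
the parents). Region dummies use the discrete counterfactual contrast
against the reference region (all dummies zero). Standard errors are delta
method with analytic gradients for the fractional logit and OLS and
numerical gradients for the Tobit mean; analytic AMEs are cross-checked
against central finite differences (with interaction products recomputed
at the perturbed covariate) in the test suite and the acceptance script.

The sensitivity sweep holds every covariate at its sample mean, moves one
stressor between its 5th and 95th sample percentiles (linear-interpolation
percentiles), recomputes its interaction products consistently, and
reports predicted outcomes with delta-method SEs. Effect ratios compare
the absolute response ranges of two stressors.

### Cross-validation

Repeated k-fold CV with uniform random partitions into near-equal folds
(no stratification by default; a region-stratified option exists for
robustness checks). Errors are squared prediction errors on the percent
scale, averaged over every held-out prediction and repeat; RMSE is its
root and predictive R² is 1 − MSE/var(y) — the conventional definition,
since "cross-validated R²" has no unique formula. k defaults to 10 (the
fold count is a convention; the analysis that motivated this package did
not state one). Training folds that lose a rare region dummy entirely are
refit with that column dropped (its effect is absorbed by the reference)
and the event is counted on the report. Family rankings break MSE ties in
favour of fewer parameters.

## Stressor metrics

* DHW: Σ over a 12-week window of weekly anomalies (SST − MMM) that are
  ≥ 1 °C; smaller anomalies are rounded to zero, anomalies at or above the
  threshold contribute their full value. Exactly 12 finite weekly values
  are required — missing weeks are an error, never silently imputed.
* PAR anomaly: Σ max(0, weekly PAR − climatological maximum) over the same
  window, so zero means no radiative stress and positive values mean
  increasing stress. The baseline is the maximum over monthly
  climatologies. (Whether the source analysis accumulated the excess over
  12 weeks or used a per-week quantity is ambiguous in its description;
  accumulation, mirroring DHW, is implemented.) A 12-week raw mean is also
  provided as the alternative PAR formulation.
* Observed vs maximum: *observed* is the window ending on the survey date;
  *maximum* is the best over all windows lying inside [season start,
  survey date] (season start defaults to 2005-01-01 and is configurable).
  Maximum ≥ observed always.
* Wind: running maximum over [season start, survey date], a storm/
  hurricane-intensity proxy.
* Population density: maximum grid-cell value whose center lies within
  50 km great-circle distance; an empty disc is a coverage error.
* Distance from shore: exact great-circle point-to-polyline distance
  (cross-track distance where the projection falls inside an arc, endpoint
  distance otherwise) on a sphere of radius 6371.0088 km.

Weekly cadence is used throughout (the underlying satellite products are
twice-weekly or finer; weekly means are the natural common denominator for
a metric defined per week).

## The synthetic campaign generator

The generator is the package's study-condition definition, emulating a
Caribbean-wide bleaching-season campaign:

* ~3,000 sites in eight analysis ecoregions plus a deliberately tiny ninth
  region (5 sites) that exercises the small-region lumping rule; fixed
  island/mainland geography supplies realistic distance-from-shore (median
  ≈ 40 km) and coastal population hot spots (0.02–25 thousand people/km²).
* Weekly SST = per-site MMM + seasonal cycle peaking 0.3 °C above MMM +
  a late-summer Gaussian warm pulse whose regional mean amplitude
  (0.45–1.5 °C) spreads maximum DHW over roughly 0–15 °C-weeks, with about
  half of surveys showing no observed stress on the survey day. Alert
  levels derive from rolling DHW (0 = no stress, 1 = warning, 2 = alert),
  so the attribution filter excludes never-warned sites, as it should.
* Weekly PAR = seasonal cycle + occasional excess episodes against a
  climatological maximum baseline; wind has gamma noise and rare storm
  gusts (10–28 m/s extra).
* Outcomes: μ = G(x'β + region offset) with generating coefficients that
  echo the sign pattern and rough magnitude of published 2005-event
  estimates — this is calibration so simulated tables look like real ones,
  not ground truth. y is zero-inflated Beta with dispersion φ = 6 and zero
  mass π₀(1−μ) (π₀ = 0.5 for mortality, 0.1 for bleaching): zeros
  concentrate at low-stress sites and E[y|x] = μ holds exactly, so the
  generating β remain the estimand while the distribution is deliberately
  *not* the one any estimator assumes — the round trip tests
  quasi-likelihood robustness, not distributional luck. Cover and colony
  measurements are two multiplicative-noise replicates (SD 8%) of the
  latent outcome, recorded to 0.1 percentage point as surveys do (whence
  exact zeros below the detection resolution).

Calibration targets for the defaults, checked in the tests: median
composite bleaching ≈ 26%, median mortality 0% with mean ≈ 2%, maximum
DHW spanning ~0–15 °C-weeks.

What the generator does **not** emulate: spatially autocorrelated residual
fields beyond region offsets, observer/protocol effects beyond symmetric
replicate noise, hurricane tracks (only the max-wind proxy), non-random
site selection. Passing recovery tests therefore demonstrates correctness
of the estimators and pipeline under the assumed mean structure — not that
the real 2005 estimates are right.

## Verification design

* Stressor metrics are checked against explicit scalar-loop oracles on
  random series (agreement to 10⁻¹⁰) and property tests (monotonicity,
  maximum ≥ observed, flat-tail behaviour).
* The fractional logit and Tobit are checked against an independent
  derivative-free (Powell) maximisation of their written objectives on
  small fixtures (10⁻⁵), against statsmodels GLM/Logit/OLS where those
  overlap, and against the estimating-equation identity Σ(y−ŷ)x = 0 on
  every fit.
* Full-pipeline recovery: with the environment held fixed and outcomes
  redrawn 100 times at campaign scale (~1,800 analysis rows), 95%
  robust-CI coverage of every generating coefficient must lie in
  [90%, 99%], and analytic AMEs must match finite differences to 10⁻⁶.
* Model selection: the fractional logit must beat OLS on repeated 10-fold
  CV MSE in ≥ 90% of 50 outcome replicates (20 repeats per replicate — a
  deliberate scale-down of the 1000-repeat convention used for final
  reported fits, which only tightens the MSE average, not its location).

## Known limitations

* The robust-covariance flavour (HC1, unclustered) is a default, not the
  only defensible choice; region clustering typically widens regional SEs.
* The Tobit sandwich uses a finite-difference Hessian; extremely small σ
  (near-degenerate censoring) is flagged as non-converged rather than
  resolved.
* CV treats observations as exchangeable; with strong within-region
  correlation, fold-level independence is optimistic (the stratified
  option mitigates but does not remove this).
* The generator's effect-ratio between temperature and population density
  is an emergent property of its calibrated coefficients and covariate
  ranges; it is reported by the acceptance script as computed, typically
  between ~4 and ~10 depending on seed and outcome.
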