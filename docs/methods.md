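# Methods

This note records the statistical model, the defaults and why they are
set as they are, the numerical choices, and the known limitations of the
package.  It is the design rationale in one place; the README gives the
user-facing overview.

## The trial-level surrogacy model

The unit of analysis is a randomized comparison summarized by two hazard
ratios: the surrogate endpoint (rPFS) and the true endpoint (OS).  Both
are log-transformed; the linearity assumption for the relation between
treatment effects is stated on that scale.  Standard errors come from
the published confidence limits, `se = (ln u − ln l)/(2 z)`, with the
exact normal quantile `z = 1.9599640` at the 95% level rather than the
rounded 1.96 — a 0.002% effect, kept exact so derived quantities
reconcile.  Hazard ratios are used at their printed precision; nothing
is re-rounded before the log transform.

Two estimators of the trial-level association are deliberately kept
side by side, since they answer the question with different assumptions:

**BRMA.**  The observed pair is bivariate normal around the trial's true
effects with *known* within-study covariance; true effects are bivariate
normal across trials.  The between-study correlation ρ is the surrogacy
parameter and `R² = ρ²`.  The within-study correlation between the two
endpoints' estimation errors is not identifiable from published
summaries (it would require patient-level data or bootstrap resampling
within each trial); the model takes it as an input, default 0, with a
documented sensitivity sweep over {0, 0.3, 0.5, 0.7} available through
`within_corr`.  This matters: on the packaged table it moves the implied
regression slope by a few hundredths.

**WLR.**  Inverse-variance weighted least squares of `y2` on `y1`.
"Inverse variance" is read as the regressand's precision, `1/se(y2)²`
(`weight_scheme="inv_var_true"`); total-variance weights
`1/(se1²+se2²)`, sample-size weights and equal weights are selectable.
The weighted R² is the squared weighted Pearson correlation of the
observed pairs, which for a one-covariate model equals the regression's
weighted coefficient of determination (both are computed and asserted
equal to 1e-10 as an internal consistency check).  Because the
regressor is itself measured with error, the WLS slope is attenuated;
`attenuation_correction=True` divides out the regression-dilution
factor `(Sxx/Sw − mean_w(se1²))/(Sxx/Sw)`.  With total-variance weights
this errors-in-variables slope is the moment analogue of regressing the
*true* OS effect on the *true* rPFS effect.  It is not the default
because the default chain (weights, R², STE) is kept as one coherent
set; it exists because regressions published in this literature often
embed exactly such a correction implicitly.

## Boundary degeneracy of the likelihood

With the number of trials meta-analyses actually have (here 8–11), the
restricted likelihood in ρ is often maximized at |ρ| = 1: the
between-study signal is compatible with a perfectly correlated pair of
random effects once within-study noise has absorbed the scatter.  On
the packaged table this happens for every analysis set and every
within-study correlation in the sweep — REML and ML alike (verified
against an independent multivariate meta-analysis implementation, which
agrees with this package's optimum to five decimals in every
parameter).  The package treats the boundary as a *reportable result*,
not an error: `BRMAResults.boundary` is set, `R² = 1.0` is returned,
and interval methods switch from the Fisher-z/observed-information
construction (whose information matrix is singular at the boundary) to
a seeded parametric bootstrap.  Analyses that report interior estimates
of ρ from tables like this one are generally using Bayesian posterior
summaries, where the prior keeps ρ off the boundary; a Bayesian BRMA is
out of scope here (a possible future option), and users should read
`boundary=True` as "the data do not identify ρ away from 1 under the
likelihood", not as evidence of perfect surrogacy.

Parameterization and optimization: `(log τ1, log τ2, atanh ρ)`
guarantees an admissible covariance; pooled means are profiled out by
GLS.  Multistart (five fixed starts plus a moment start) L-BFGS-B with
`gtol 1e-10`, followed by a Nelder–Mead polish of the best candidate
(`fatol 1e-13`); ties broken by objective, then smallest parameter
norm.  τ is floored at 1e-6 (a boundary solution is reported, never an
error); |atanh ρ| is capped at 18, i.e. |ρ| ≤ 1 − 4e-16.

## Prediction and LOOCV

The conditional law of a new trial's observable OS effect given its
observed rPFS effect is normal with

    m = μ2 + c12/(τ1² + se1²) · (y1 − μ1),      c12 = ρτ1τ2 + w·se1·se2
    v = (τ2² + se2²) − c12²/(τ1² + se1²)

— the exact bivariate-normal conditional, so the shrinkage denominator
includes the new trial's surrogate measurement error and the variance
includes its OS measurement error.  LOOCV refits the BRMA without each
trial and applies this formula at the left-out trial's values; accuracy
is the proportion of observed OS effects inside the 95% intervals.

Parameter-estimation uncertainty can be added to the predictive
variance by the delta method (`include_param_uncertainty=True`); the
default leaves it out.  The choice is consequential at the margin: on
the packaged primary set one trial (PREVAIL) sits 0.007 log-HR units
outside its uninflated interval, so inflating the variance flips the
accuracy from 8/10 to 9/10.  The uninflated conditional interval is the
default because it is the exact predictive law of the fitted model —
the quantity LOOCV is meant to calibrate — and because calibration
simulations from the fitted model reproduce the nominal 95% coverage
without inflation.  Both variants are computed behind the flag.

## Surrogate threshold effect

The STE inverts the upper 95% limit of a band around the WLR line at
the OS null: the largest `x = ln HR_rPFS` with `upper(x) = 0`, found by
bisection on the bracket `[ln 1e-3, 0]` to `|f| < 1e-10`; `STE =
exp(x)`.  Two bands are available:

* `band="confidence"` (default): the band for the *conditional mean*
  OS effect, `ŷ(x) ± t(n−2)·sqrt(s²·(1/Σw + (x−x̄w)²/Sxx_w))`, with
  `s²` the weighted mean squared error.  Rationale: the decision rule
  applied to a future trial compares the trial's own *upper CI limit*
  of its rPFS HR to the STE — the new trial's sampling noise enters
  through its own confidence interval, so the band should carry only
  the uncertainty about the line.  This is also the prediction band of
  a weighted meta-regression with Knapp–Hartung scaling when the
  residual heterogeneity estimate is zero, as it is on the packaged
  table.
* `band="prediction"`: adds a new-trial variance component `s²/w_new`,
  with `w_new` the mean observed weight (`new_weight_rule=
  "mean_weight"`) or 1 on the weighted scale (`"unit_weight"`).  This
  is the conservative choice when the rule is applied to a point
  estimate rather than a confidence limit; on the packaged table it
  moves the STE from 0.83 to roughly 0.49.

t(n−2) quantiles are the default (n is ~10); normal quantiles are
selectable (`df_rule="normal"`).  A threshold beyond HR = 1 —
analytically legitimate in near-noiseless data with a negative
intercept — is reported as solvable with an `exceeds_null` flag rather
than suppressed, because it is clinically nonsensical and must be
visible.  STE monotonicity (more scatter ⇒ a stricter threshold) and
exact consistency between `compute_ste` and the band it inverts
(`|upper(x*)| < 1e-8`) are enforced by tests.

## Outlier flagging and analysis sets

The scatterplot outlier rule flags trials whose OS effect falls outside
the WLR band at their rPFS effect.  The band is configurable
(prediction default; confidence selectable).  On the packaged 11-trial
table the prediction-band default flags NCT02294461 only, and
confidence-band variants flag supersets including ACIS; no 95% band
choice isolates exactly the two trials conventionally treated as
outlying (NCT02294461 and ERA 223), whose designation was ultimately
visual.  The analysis-set definitions therefore do not depend on the
flagging operation: `sensitivity_2` removes a *configured* outlier list
(default: those two trials), so downstream results are reproducible
regardless of band choice.  A PH violation on either endpoint excludes
a trial from the primary set; per-endpoint flags are stored.

## Synthetic data and what passing tests show

The generator draws true surrogate effects `θ1 ~ N(β1, τ1²)`, places
true OS effects on a line `θ2 = α + β·θ1 + N(0, ψ²)`, and adds
within-study noise with SEs drawn uniformly from configurable ranges —
defaults `se1 ∈ [0.05, 0.20]`, `se2 ∈ [0.06, 0.37]`, the span observed
in the packaged table, so synthetic data stress the same information
regime.  Parameterizing by (intercept, slope, residual SD) keeps the
implied `R² = β²τ1²/(β²τ1² + ψ²)` explicit; converters to and from
(τ2, ρ) are provided.  Replicate seeds are derived counter-style from
`(seed, replicate)` so experiments are reproducible and replicates
independent.

What the generator does *not* emulate: non-proportional hazards (PH
status is an input flag, never generated), correlation induced by
shared control arms, published-CI rounding, selective reporting, and
follow-up-dependent censoring.  Passing recovery and calibration tests
therefore show the estimators are correct *under the stated model*, not
that real trial networks satisfy it.

Problem sizes used in the shipped validation suite: oracle equivalence
on 5–6 trial toys against a coarse-to-fine brute-force grid (6 zoom
rounds, 9 points per axis, agreement to 1e-3 per parameter); parameter
recovery with 500 replicates of 10-trial meta-analyses per true R² in
{0.2, 0.5, 0.8} with small within-study SEs (0.02–0.05) — the
information regime in which R² recovery is meaningful at n = 10, where
the intrinsic small-sample bias of a squared correlation is already
≈ +0.06 at R² = 0.2; interval coverage with 300 replicates; LOOCV
calibration on an 80-trial meta-analysis generated from the model
fitted to the packaged table.

## Known limitations

* The frequentist likelihood cannot report an interior between-study
  correlation on datasets like the packaged one (see boundary section);
  only interval methods convey the uncertainty in R² there.
* The Fisher-z interval for the BRMA R² relies on the observed
  information at an interior optimum; near the boundary the bootstrap
  fallback is used and is the slowest path in the package.
* Within-study correlation is a fixed input, not estimated.
* The STE depends visibly on band conventions (documented above); any
  single number should be quoted together with its band and quantile
  rule.
* No patient-level surrogacy (copulas, Kendall's τ), no network
  meta-analysis, no Bayesian estimation.
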