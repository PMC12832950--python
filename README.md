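# surrogateval

Trial-level surrogate-endpoint validation from published hazard ratios.

Oncology trials increasingly read out on earlier endpoints than overall
survival (OS).  Whether such an endpoint — here radiographic
progression-free survival (rPFS) in first-line, ARPi-naive metastatic
castration-resistant prostate cancer (mCRPC) — is a *valid surrogate*
for OS is a trial-level question: across randomized trials, do treatment
effects on the surrogate predict treatment effects on OS?  This package
answers it from nothing more than each trial's published hazard ratios
(HR) with 95% confidence intervals, the situation HTA agencies such as
IQWiG actually face.

## Methods at a glance

Effects are analyzed as log hazard ratios, `y = ln HR`, with standard
errors recovered from the CI, `se = (ln u − ln l) / (2 · 1.959964)`.
Writing `y1` for the surrogate (rPFS) and `y2` for the true endpoint
(OS) effect of a trial:

* **Bivariate random-effects meta-analysis (BRMA).**
  `(y1i, y2i) ~ N2(θi, Si)` within trial and
  `θi ~ N2((μ1, μ2), Σ)` between trials, with
  `Σ = [[τ1², ρτ1τ2], [ρτ1τ2, τ2²]]`.  The between-study correlation ρ
  is the trial-level surrogacy parameter; `R² = ρ²`.  Fitted by REML
  (ML optional) over `(log τ1, log τ2, atanh ρ)` with multistart
  quasi-Newton optimization.
* **Weighted linear regression (WLR).**
  `y2 = a + b·y1` by inverse-variance weighted least squares
  (default weights `1/se(y2)²`), with the weighted `R²` and a bootstrap
  or Fisher-z confidence interval.  An errors-in-variables option
  corrects the slope for regression dilution from the within-study
  error of `y1`.
* **IQWiG classification.**  On the R scale: *high* when the lower 95%
  limit of R is ≥ 0.85, *low* when the upper limit is ≤ 0.70, *medium*
  otherwise.
* **Surrogate threshold effect (STE).**  The largest surrogate HR at
  which the upper 95% limit of the band around the regression still
  excludes a null OS effect; a new trial whose rPFS HR upper confidence
  limit falls below the STE is predicted to achieve a significant OS
  benefit.
* **Leave-one-out cross-validation (LOOCV).**  Each trial's OS effect is
  predicted from a BRMA refitted without it, conditioned on its rPFS
  effect; accuracy is the share of observed effects inside their 95%
  prediction intervals.

The 11-trial summary-effect table for first-line mCRPC (ACIS, Alliance
A031201, COU-AA-302, PEACEIII, ERA 223, IPATential150, KEYNOTE-641,
NCT02294461, PREVAIL, PROpel, TALAPRO-2) ships as a packaged fixture,
along with the named analysis sets: `primary` (10 PH-compliant trials),
`sensitivity_1` (all 11), `sensitivity_2` (8, additionally dropping the
two outlying trials).  A synthetic-data module generates tables with
known surrogacy structure for estimator validation.

## Worked example

```python
import surrogateval as sv

records = sv.fixture_table()                 # the packaged 11-trial table
report = sv.run_analysis(records, "primary") # PH-compliant trials
print(report.summary())
```

prints (abridged):

```
Surrogacy evaluation: primary (10 trials, 9481 patients)

Bivariate random-effects meta-analysis (REML, 10 trials)
  pooled log HR   surrogate -0.4126   true -0.1488
  between-study SD tau1 0.4445   tau2 0.1368
  between-study correlation rho +1.0000   R^2 1.0000   [boundary]
  implied line: logHR_true = -0.0218 + 0.3079 * logHR_surr
  R^2 1.00 (0.54, 1.00) -> IQWiG medium

Weighted linear regression (inv_var_true, 10 trials)
  logHR_true = -0.0237 + 0.3037 * logHR_surrogate
  weighted R^2 0.6311   residual scale 1.1496
  R^2 0.63 (0.11, 0.90) -> IQWiG medium

Overall IQWiG class: medium
STE: HR = 0.83 [required (medium correlation)]
LOOCV accuracy: 80% (8/10)
```

Reading the numbers: the WLR finds that 63% of the variability in OS
effects is explained by rPFS effects — a *medium* correlation under
IQWiG rules, so surrogacy conclusions go through the STE: a future trial
whose rPFS HR upper confidence limit is below 0.83 would be predicted to
show a significant OS benefit.  LOOCV places 8 of 10 observed OS effects
inside their 95% prediction intervals.  The REML BRMA sits on the
`rho = 1` boundary — with ten trials the restricted likelihood is
maximized at a degenerate between-study correlation, which the results
object flags (`boundary=True`); see `docs/methods.md` for why this
happens and how the bootstrap interval is produced in that case.

The same pipeline is available from the shell:

```sh
surrogate-eval run --set primary --out report.json --plots figures/
surrogate-eval dump-fixture --out trials.csv    # the expected CSV schema
surrogate-eval simulate --seed 7 --out sim.csv
surrogate-eval recover --reps 200 --seed 7 --out recovery.csv
```

## Layout

```
src/surrogateval/
  trial_data.py      records, CSV I/O, log-scale conversion, analysis sets
  brma.py            BivariateEffectsMeta model + BRMAResults
  wlr_ste.py         SurrogateRegression model + WLRResults, SteResult
  loocv.py           leave-one-out cross-validation
  surrogacy.py       IQWiG rules, outlier flagging, orchestrated report
  synthetic_data.py  generator with known trial-level R², recovery loops
  plots.py, cli.py   figures and the surrogate-eval entry point
```
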