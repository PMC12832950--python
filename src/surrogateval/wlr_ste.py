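"""Weighted linear regression of true-endpoint on surrogate log HRs, and
the surrogate threshold effect (STE).

The regression ``y2 = a + b*y1`` is fitted by inverse-variance weighted
least squares across trials.  ``r2_weighted`` is the squared weighted
Pearson correlation of the observed pairs, which for this one-covariate
model coincides with the regression's weighted coefficient of
determination (both are computed and cross-checked).

The STE is the largest (closest to null) surrogate hazard ratio at which
the upper limit of the 95% band around the regression still excludes a
null effect on the true endpoint: a new trial whose surrogate effect is
convincingly below the STE (upper CI limit of its rPFS HR < STE) is
predicted to achieve a significant true-endpoint benefit.  By default
the inverted band is the *confidence* band for the conditional mean with
t(n-2) quantiles and the weighted mean squared error as scale — the new
trial's own sampling noise enters the decision rule through its own CI,
not through the band.  Prediction-band variants (adding a new-trial
variance component) are available for sensitivity analysis.

An optional regression-dilution (errors-in-variables) correction divides
the slope's attenuation by the within-study variance of the surrogate
effects; with total-variance weights this reproduces regressions that
treat both endpoints' effects as measured with error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .brma import IntervalEstimate
from .trial_data import EffectPair

__all__ = [
    "SurrogateRegression",
    "WLRResults",
    "SteResult",
    "fit_wlr",
    "wlr_r2_interval",
    "prediction_interval",
    "compute_ste",
]

_WEIGHT_SCHEMES = ("inv_var_true", "inv_var_sum", "sample_size", "equal")


@dataclass(frozen=True)
class SteResult:
    """Surrogate threshold effect on the HR scale.

    ``solvable`` is False when the band never crosses the null over
    HR in (0, 1); ``exceeds_null`` flags the analytically legitimate but
    clinically nonsensical case STE > 1 (band above null everywhere in
    (0, 1) yet crossing beyond it).
    """

    ste_hr: float | None
    x_threshold: float | None
    level: float
    band: str
    df_rule: str
    solvable: bool
    exceeds_null: bool = False
    message: str = ""


class SurrogateRegression:
    """Inverse-variance weighted regression of log HR_true on log HR_surrogate.

    weight_scheme
        ``inv_var_true``: 1/se2^2 (default; the regressand's precision),
        ``inv_var_sum``: 1/(se1^2 + se2^2), ``sample_size``: n_i (needs
        ``sizes``), ``equal``: ordinary least squares.
    attenuation_correction
        Divide out the regression-dilution factor caused by within-study
        error in the surrogate effects (slope inflated accordingly; the
        intercept keeps the line through the weighted mean point).
    """

    def __init__(
        self,
        effects: list[EffectPair],
        weight_scheme: str = "inv_var_true",
        sizes: list[int] | None = None,
        attenuation_correction: bool = False,
    ):
        if len(effects) < 3:
            raise ValueError("need at least 3 trials for WLR")
        if weight_scheme not in _WEIGHT_SCHEMES:
            raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
        self.effects = list(effects)
        self.weight_scheme = weight_scheme
        self.attenuation_correction = bool(attenuation_correction)
        self._y1 = np.array([e.y1 for e in effects])
        self._se1 = np.array([e.se1 for e in effects])
        self._y2 = np.array([e.y2 for e in effects])
        self._se2 = np.array([e.se2 for e in effects])
        if weight_scheme == "inv_var_true":
            w = 1.0 / self._se2**2
        elif weight_scheme == "inv_var_sum":
            w = 1.0 / (self._se1**2 + self._se2**2)
        elif weight_scheme == "sample_size":
            if sizes is None:
                raise ValueError("sample_size weights need per-trial sizes")
            w = np.asarray(sizes, dtype=float)
        else:
            w = np.ones(len(effects))
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
        self._w = w

    def fit(self) -> "WLRResults":
        y1, y2, w = self._y1, self._y2, self._w
        sw = w.sum()
        xbar = (w * y1).sum() / sw
        ybar = (w * y2).sum() / sw
        sxx = (w * (y1 - xbar) ** 2).sum()
        sxy = (w * (y1 - xbar) * (y2 - ybar)).sum()
        syy = (w * (y2 - ybar) ** 2).sum()
        if sxx <= 1e-12 * sw * max(1.0, float(np.max(np.abs(y1))) ** 2):
            raise ValueError("degenerate design: surrogate effects all identical")
        if self.attenuation_correction:
            me = (w * self._se1**2).sum() / sw  # weighted mean within-var of y1
            sxx_latent = sxx / sw - me
            if sxx_latent <= 0:
                raise ValueError(
                    "within-study error exceeds surrogate-effect spread; "
                    "attenuation correction undefined"
                )
            slope = (sxy / sw) / sxx_latent
        else:
            slope = sxy / sxx
        intercept = ybar - slope * xbar
        n = len(y1)
        resid = y2 - intercept - slope * y1
        residual_scale = (w * resid**2).sum() / (n - 2)
        # weighted Pearson^2 of the observed pairs ...
        r2_corr = sxy**2 / (sxx * syy)
        # ... equals the WLS coefficient of determination (one covariate)
        b_wls = sxy / sxx
        rss = (w * (y2 - (ybar - b_wls * xbar) - b_wls * y1) ** 2).sum()
        r2_det = 1.0 - rss / syy
        assert abs(r2_corr - r2_det) < 1e-10
        return WLRResults(
            intercept=float(intercept),
            slope=float(slope),
            weights=w.copy(),
            weight_scheme=self.weight_scheme,
            residual_scale=float(residual_scale),
            sum_w=float(sw),
            xbar_w=float(xbar),
            sxx_w=float(sxx),
            n_trials=n,
            r2_weighted=float(r2_corr),
            attenuation_corrected=self.attenuation_correction,
            model=self,
        )


@dataclass
class WLRResults:
    intercept: float
    slope: float
    weights: np.ndarray
    weight_scheme: str
    residual_scale: float
    sum_w: float
    xbar_w: float
    sxx_w: float
    n_trials: int
    r2_weighted: float
    attenuation_corrected: bool = False
    model: SurrogateRegression = field(repr=False, default=None)

    def predict(self, x0):
        return self.intercept + self.slope * np.asarray(x0, dtype=float)

    def _band_halfwidth(self, x0, level, band, new_weight_rule, df_rule):
        if df_rule == "t_nminus2":
            q = stats.t.ppf(0.5 + level / 2.0, self.n_trials - 2)
        elif df_rule == "normal":
            q = stats.norm.ppf(0.5 + level / 2.0)
        else:
            raise ValueError(f"unknown df_rule {df_rule!r}")
        x0 = np.asarray(x0, dtype=float)
        var = 1.0 / self.sum_w + (x0 - self.xbar_w) ** 2 / self.sxx_w
        if band == "prediction":
            if new_weight_rule == "mean_weight":
                w_new = float(np.mean(self.weights))
            elif new_weight_rule == "unit_weight":
                w_new = 1.0
            else:
                raise ValueError(f"unknown new_weight_rule {new_weight_rule!r}")
            var = var + 1.0 / w_new
        elif band != "confidence":
            raise ValueError(f"unknown band {band!r}")
        return q * np.sqrt(self.residual_scale * var)

    def prediction_interval(
        self,
        x0,
        level: float = 0.95,
        band: str = "prediction",
        new_weight_rule: str = "mean_weight",
        df_rule: str = "t_nminus2",
    ):
        """Band around the regression at ``x0`` (log HR scale).

        ``band="prediction"`` (default) adds a new-trial variance
        component ``residual_scale / w_new`` under ``new_weight_rule``;
        ``band="confidence"`` is the band for the conditional mean.
        """
        half = self._band_halfwidth(x0, level, band, new_weight_rule, df_rule)
        center = self.predict(x0)
        return center - half, center + half

    def r2_interval(
        self,
        level: float = 0.95,
        method: str = "fisher_z",
        n_boot: int = 2000,
        seed: int | None = None,
    ) -> IntervalEstimate:
        """CI for the weighted R^2: Fisher-z on the weighted correlation
        (nominal se 1/sqrt(n-3)) or a seeded trial-resampling bootstrap."""
        point = self.r2_weighted
        n = self.n_trials
        if method == "fisher_z":
            if n < 4:
                raise ValueError("fisher_z interval needs >= 4 trials")
            r = np.sqrt(point) * np.sign(self.slope)
            z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
            q = stats.norm.ppf(0.5 + level / 2.0)
            se = 1.0 / np.sqrt(n - 3)
            lo_r, hi_r = np.tanh(z - q * se), np.tanh(z + q * se)
            bounds = sorted((lo_r**2, hi_r**2))
            if lo_r < 0 < hi_r:
                bounds[0] = 0.0
            return IntervalEstimate(
                point, min(bounds[0], point), max(bounds[1], point), level, "fisher_z"
            )
        if method == "bootstrap":
            rng = np.random.default_rng(seed)
            eff = self.model.effects
            r2s = []
            for _ in range(n_boot):
                idx = rng.integers(0, n, size=n)
                sample = [eff[i] for i in idx]
                try:
                    fit = SurrogateRegression(
                        sample,
                        weight_scheme=self.weight_scheme,
                        attenuation_correction=self.attenuation_corrected,
                    ).fit()
                except (ValueError, AssertionError):
                    continue
                r2s.append(fit.r2_weighted)
            alpha = 1.0 - level
            lo, hi = np.quantile(r2s, [alpha / 2, 1 - alpha / 2])
            return IntervalEstimate(
                point, float(min(lo, point)), float(max(hi, point)), level, "bootstrap"
            )
        raise ValueError(f"unknown method {method!r}")

    def compute_ste(
        self,
        level: float = 0.95,
        band: str = "confidence",
        new_weight_rule: str = "mean_weight",
        df_rule: str = "t_nminus2",
    ) -> SteResult:
        """Invert the upper band limit at the true-endpoint null.

        Finds the largest log surrogate HR ``x < ln(bracket upper)`` with
        ``upper_band(x) = 0`` by bisection over HR in [1e-3, 1]; reports
        ``ste_hr = exp(x)``.  A positive slope (benefit on the surrogate
        predicting benefit on the true endpoint) is required.
        """
        if self.slope <= 0:
            return SteResult(None, None, level, band, df_rule, False,
                             message="non-positive slope; STE undefined")

        def upper(x):
            return float(
                self.predict(x)
                + self._band_halfwidth(x, level, band, new_weight_rule, df_rule)
            )

        lo, hi = np.log(1e-3), 0.0
        if upper(lo) > 0:
            return SteResult(None, None, level, band, df_rule, False,
                             message="band never crosses the null for HR in (0, 1)")
        if upper(hi) < 0:
            # crossing sits beyond HR = 1: extend the bracket to report it
            hi_ext = hi
            while upper(hi_ext) < 0 and hi_ext < 5:
                hi_ext += 0.5
            if upper(hi_ext) < 0:
                return SteResult(None, None, level, band, df_rule, False,
                                 message="band upper limit negative everywhere")
            x = optimize.brentq(upper, hi, hi_ext, xtol=1e-12)
            return SteResult(float(np.exp(x)), float(x), level, band, df_rule,
                             True, exceeds_null=True,
                             message="threshold exceeds the null HR of 1")
        x = optimize.brentq(upper, lo, hi, xtol=1e-12)
        return SteResult(float(np.exp(x)), float(x), level, band, df_rule, True)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "weight_scheme": self.weight_scheme,
            "attenuation_corrected": self.attenuation_corrected,
            "residual_scale": self.residual_scale,
            "n_trials": self.n_trials,
            "r2_weighted": self.r2_weighted,
        }

    def summary(self) -> str:
        return "\n".join(
            [
                f"Weighted linear regression ({self.weight_scheme},"
                f" {self.n_trials} trials"
                + (", attenuation-corrected" if self.attenuation_corrected else "")
                + ")",
                f"  logHR_true = {self.intercept:+.4f} + {self.slope:.4f}"
                " * logHR_surrogate",
                f"  weighted R^2 {self.r2_weighted:.4f}"
                f"   residual scale {self.residual_scale:.4f}",
            ]
        )


# -- thin functional wrappers (spec-style operation names) -------------------

def fit_wlr(
    effects: list[EffectPair],
    weight_scheme: str = "inv_var_true",
    sizes=None,
    attenuation_correction: bool = False,
) -> WLRResults:
    return SurrogateRegression(
        effects, weight_scheme=weight_scheme, sizes=sizes,
        attenuation_correction=attenuation_correction,
    ).fit()


def wlr_r2_interval(fit: WLRResults, level=0.95, method="fisher_z",
                    n_boot=2000, seed=None) -> IntervalEstimate:
    return fit.r2_interval(level=level, method=method, n_boot=n_boot, seed=seed)


def prediction_interval(fit: WLRResults, x0, level=0.95, band="prediction",
                        new_weight_rule="mean_weight", df_rule="t_nminus2"):
    return fit.prediction_interval(x0, level, band, new_weight_rule, df_rule)


def compute_ste(fit: WLRResults, level=0.95, band="confidence",
                new_weight_rule="mean_weight", df_rule="t_nminus2") -> SteResult:
    return fit.compute_ste(level, band, new_weight_rule, df_rule)
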