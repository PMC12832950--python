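"""Bivariate random-effects meta-analysis (BRMA) of paired log hazard ratios.

Model.  For trial *i* the observed log-HR pair ``(y1i, y2i)`` is normal
around the trial's true effects with known within-study covariance
``S_i = [[se1i^2, w*se1i*se2i], [w*se1i*se2i, se2i^2]]`` (``w`` the assumed
within-study correlation, 0 by default since it is not estimable from
published summaries).  True effects are bivariate normal across trials,

    (theta1i, theta2i) ~ N2((mu1, mu2), Sigma),
    Sigma = [[tau1^2, rho*tau1*tau2], [rho*tau1*tau2, tau2^2]].

The between-study correlation ``rho`` measures trial-level surrogacy;
``R^2 = rho^2`` is the share of variability in true-endpoint effects
explained by surrogate effects.  The marginal likelihood (restricted by
default) is maximized over ``(log tau1, log tau2, atanh rho)`` with the
pooled means profiled out by GLS, from multiple starting points.

With as few trials as meta-analyses typically have, the likelihood can
be maximized on the boundary ``|rho| = 1``; such fits are reported with
``boundary=True`` rather than raised as errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trial_data import EffectPair

__all__ = [
    "BivariateEffectsMeta",
    "BRMAResults",
    "IntervalEstimate",
    "fit_brma",
    "r2_interval",
    "implied_line",
    "predict_new",
]

_LOG2PI = np.log(2.0 * np.pi)
_TAU_FLOOR = 1e-6
_Z_CAP = 18.0  # |atanh rho| cap; tanh(18) = 1 - 4e-16


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "fisher_z"

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise ValueError("interval must bracket the point estimate")


def _as_arrays(effects):
    y = np.array([[e.y1, e.y2] for e in effects], dtype=float)
    se = np.array([[e.se1, e.se2] for e in effects], dtype=float)
    if not np.all(np.isfinite(y)) or np.any(se <= 0):
        raise ValueError("effects must have finite y and positive se")
    return y, se


def _marginal_cov(se, within_corr, t1, t2, rho):
    """Per-trial 2x2 marginal covariance entries (vectorized)."""
    v11 = se[:, 0] ** 2 + t1 * t1
    v22 = se[:, 1] ** 2 + t2 * t2
    v12 = within_corr * se[:, 0] * se[:, 1] + rho * t1 * t2
    return v11, v12, v22


def _profile_nll(p, y, se, within_corr, reml):
    """Negative (restricted) log-likelihood with GLS-profiled means."""
    t1, t2 = np.exp(p[0]), np.exp(p[1])
    rho = np.tanh(p[2])
    v11, v12, v22 = _marginal_cov(se, within_corr, t1, t2, rho)
    det = v11 * v22 - v12 * v12
    if np.any(det <= 0):
        return np.inf
    i11, i12, i22 = v22 / det, -v12 / det, v11 / det
    # GLS mean: A = sum V_i^{-1}, b = sum V_i^{-1} y_i
    a11, a12, a22 = i11.sum(), i12.sum(), i22.sum()
    b1 = (i11 * y[:, 0] + i12 * y[:, 1]).sum()
    b2 = (i12 * y[:, 0] + i22 * y[:, 1]).sum()
    det_a = a11 * a22 - a12 * a12
    if det_a <= 0:
        return np.inf
    mu1 = (a22 * b1 - a12 * b2) / det_a
    mu2 = (a11 * b2 - a12 * b1) / det_a
    r1, r2_ = y[:, 0] - mu1, y[:, 1] - mu2
    quad = (i11 * r1 * r1 + 2.0 * i12 * r1 * r2_ + i22 * r2_ * r2_).sum()
    n = y.shape[0]
    nll = 0.5 * (2 * n * _LOG2PI + np.log(det).sum() + quad)
    if reml:
        nll += 0.5 * (np.log(det_a) - 2.0 * _LOG2PI)
    return nll


def _gls_mean(p, y, se, within_corr):
    t1, t2 = np.exp(p[0]), np.exp(p[1])
    rho = np.tanh(p[2])
    v11, v12, v22 = _marginal_cov(se, within_corr, t1, t2, rho)
    det = v11 * v22 - v12 * v12
    i11, i12, i22 = v22 / det, -v12 / det, v11 / det
    a = np.array([[i11.sum(), i12.sum()], [i12.sum(), i22.sum()]])
    b = np.array(
        [(i11 * y[:, 0] + i12 * y[:, 1]).sum(), (i12 * y[:, 0] + i22 * y[:, 1]).sum()]
    )
    return np.linalg.solve(a, b)


def _moment_start(y, se):
    """Moment estimates (WLR-style) used as one multistart point."""
    c = np.cov(y.T)
    t1sq = max(c[0, 0] - np.mean(se[:, 0] ** 2), 1e-4)
    t2sq = max(c[1, 1] - np.mean(se[:, 1] ** 2), 1e-4)
    rho = np.clip(c[0, 1] / np.sqrt(t1sq * t2sq), -0.95, 0.95)
    return [0.5 * np.log(t1sq), 0.5 * np.log(t2sq), np.arctanh(rho)]


@dataclass
class BRMAResults:
    """Fitted BRMA: pooled means, heterogeneity SDs, between-study correlation."""

    mu1: float
    mu2: float
    tau1: float
    tau2: float
    rho: float
    loglik: float
    converged: bool
    boundary: bool
    n_trials: int
    within_corr: float
    method: str
    model: "BivariateEffectsMeta" = field(repr=False, default=None)

    @property
    def r2(self) -> float:
        return self.rho**2

    @property
    def params(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.tau1, self.tau2, self.rho])

    # -- derived quantities -------------------------------------------------

    def implied_line(self) -> tuple[float, float]:
        """Between-study conditional-mean line of theta2 given theta1.

        Returns ``(intercept, slope)`` with ``slope = rho*tau2/tau1``.
        """
        if self.tau1 <= _TAU_FLOOR:
            raise ValueError("surrogate effects homogeneous; line undefined")
        slope = self.rho * self.tau2 / self.tau1
        return self.mu2 - slope * self.mu1, slope

    def predict_new(
        self,
        y1_new: float,
        se1_new: float,
        se2_new: float = 0.0,
        level: float = 0.95,
        include_param_uncertainty: bool = False,
    ) -> tuple[float, float, float]:
        """Predict a new trial's true-endpoint log HR from its surrogate effect.

        Conditions the fitted bivariate normal for the observable pair on
        the new trial's observed surrogate effect ``y1_new`` (measured
        with error ``se1_new``); the returned variance includes the new
        trial's within-study true-endpoint error ``se2_new``.  Returns
        ``(mean, lower, upper)``.  ``include_param_uncertainty`` adds
        delta-method variance for the estimated model parameters.
        """
        t1, t2, rho, w = self.tau1, self.tau2, self.rho, self.within_corr
        v11 = t1 * t1 + se1_new * se1_new
        c12 = rho * t1 * t2 + w * se1_new * se2_new
        m = self.mu2 + c12 / v11 * (y1_new - self.mu1)
        v = (t2 * t2 + se2_new * se2_new) - c12 * c12 / v11
        if v < 0:
            warnings.warn("negative conditional variance clipped at 0")
            v = 0.0
        if include_param_uncertainty:
            v += self._param_uncertainty_variance(y1_new, se1_new, se2_new)
        q = stats.norm.ppf(0.5 + level / 2.0)
        half = q * np.sqrt(v)
        return float(m), float(m - half), float(m + half)

    def _param_uncertainty_variance(self, y1_new, se1_new, se2_new) -> float:
        """Delta-method variance of the conditional mean in the fit parameters."""
        cov = self._param_cov()
        if cov is None:
            return 0.0

        def mean_of(q):
            mu1, mu2 = q[0], q[1]
            t1, t2 = np.exp(q[2]), np.exp(q[3])
            rho = np.tanh(q[4])
            c12 = rho * t1 * t2 + self.within_corr * se1_new * se2_new
            return mu2 + c12 / (t1 * t1 + se1_new * se1_new) * (y1_new - mu1)

        q0 = self._internal_params()
        grad = optimize.approx_fprime(q0, mean_of, 1e-6)
        return float(grad @ cov @ grad)

    def _internal_params(self) -> np.ndarray:
        z = np.arctanh(np.clip(self.rho, -1 + 1e-15, 1 - 1e-15))
        return np.array(
            [self.mu1, self.mu2, np.log(self.tau1), np.log(self.tau2),
             np.clip(z, -_Z_CAP, _Z_CAP)]
        )

    def _param_cov(self):
        """Inverse observed information over (mu1, mu2, log t1, log t2, z)."""
        if self.model is None:
            return None
        y, se = self.model._y, self.model._se
        w = self.within_corr

        def nll(q):
            t1, t2 = np.exp(q[2]), np.exp(q[3])
            rho = np.tanh(q[4])
            v11, v12, v22 = _marginal_cov(se, w, t1, t2, rho)
            det = v11 * v22 - v12 * v12
            if np.any(det <= 0):
                return np.inf
            r1, r2_ = y[:, 0] - q[0], y[:, 1] - q[1]
            quad = (v22 * r1 * r1 - 2 * v12 * r1 * r2_ + v11 * r2_ * r2_) / det
            return 0.5 * (np.log(det).sum() + quad.sum())

        q0 = self._internal_params()
        hess = _numerical_hessian(nll, q0)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            return None
        return cov

    # -- intervals ----------------------------------------------------------

    def r2_interval(
        self,
        level: float = 0.95,
        method: str = "fisher_z",
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> IntervalEstimate:
        """Confidence interval for the trial-level R^2 (= rho^2).

        ``fisher_z`` uses the delta method on ``atanh(rho)`` with the
        inverse observed information; near the ``|rho| = 1`` boundary the
        information is singular and the method falls back to a seeded
        parametric bootstrap (percentile interval of refitted R^2).
        """
        if method == "fisher_z" and not self.boundary:
            cov = self._param_cov()
            if cov is not None and np.isfinite(cov[4, 4]) and cov[4, 4] > 0:
                z = np.arctanh(np.clip(self.rho, -1 + 1e-15, 1 - 1e-15))
                q = stats.norm.ppf(0.5 + level / 2.0)
                se_z = np.sqrt(cov[4, 4])
                lo_r, hi_r = np.tanh(z - q * se_z), np.tanh(z + q * se_z)
                bounds = sorted((lo_r**2, hi_r**2))
                # rho CIs straddling 0 must include R^2 = 0
                if lo_r < 0 < hi_r:
                    bounds[0] = 0.0
                lo = min(bounds[0], self.r2)
                hi = max(bounds[1], self.r2)
                return IntervalEstimate(self.r2, lo, hi, level, "fisher_z")
            warnings.warn(
                "singular observed information; falling back to parametric bootstrap"
            )
        return self._bootstrap_r2(level, n_boot, seed)

    def _bootstrap_r2(self, level, n_boot, seed) -> IntervalEstimate:
        rng = np.random.default_rng(seed)
        y, se = self.model._y, self.model._se
        n = self.n_trials
        t1, t2, rho, w = self.tau1, self.tau2, self.rho, self.within_corr
        v11, v12, v22 = _marginal_cov(se, w, t1, t2, rho)
        sd1 = np.sqrt(v11)
        r2s = []
        for _ in range(n_boot):
            z1 = rng.standard_normal(n)
            z2 = rng.standard_normal(n)
            y1 = self.mu1 + sd1 * z1
            cond_sd = np.sqrt(np.maximum(v22 - v12**2 / v11, 0.0))
            y2 = self.mu2 + v12 / v11 * (y1 - self.mu1) + cond_sd * z2
            sim = [
                EffectPair(f"sim{i}", y1[i], se[i, 0], y2[i], se[i, 1])
                for i in range(n)
            ]
            try:
                fit = BivariateEffectsMeta(sim, within_corr=w).fit(
                    method=self.method,
                    starts=[self._internal_params()[2:], _moment_start(
                        np.column_stack([y1, y2]), se)],
                    polish=False,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            r2s.append(fit.r2)
        if len(r2s) < max(10, n_boot // 2):
            raise RuntimeError("parametric bootstrap failed on too many replicates")
        alpha = 1.0 - level
        lo, hi = np.quantile(r2s, [alpha / 2, 1 - alpha / 2])
        point = self.r2
        return IntervalEstimate(
            point, float(min(lo, point)), float(max(hi, point)), level,
            "parametric_bootstrap",
        )

    # -- presentation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mu1": self.mu1,
            "mu2": self.mu2,
            "tau1": self.tau1,
            "tau2": self.tau2,
            "rho": self.rho,
            "r2": self.r2,
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_trials": self.n_trials,
            "within_corr": self.within_corr,
            "method": self.method,
        }

    def summary(self) -> str:
        icept, slope = (np.nan, np.nan)
        try:
            icept, slope = self.implied_line()
        except ValueError:
            pass
        lines = [
            "Bivariate random-effects meta-analysis"
            f" ({self.method.upper()}, {self.n_trials} trials)",
            f"  pooled log HR   surrogate {self.mu1:+.4f}   true {self.mu2:+.4f}",
            f"  between-study SD tau1 {self.tau1:.4f}   tau2 {self.tau2:.4f}",
            f"  between-study correlation rho {self.rho:+.4f}   R^2 {self.r2:.4f}"
            + ("   [boundary]" if self.boundary else ""),
            f"  implied line: logHR_true = {icept:+.4f} + {slope:.4f} * logHR_surr",
            f"  log-likelihood {self.loglik:.4f}"
            + ("" if self.converged else "   [NOT CONVERGED]"),
        ]
        return "\n".join(lines)


class BivariateEffectsMeta:
    """Model object for the BRMA of paired log-HR effects.

    Parameters
    ----------
    effects
        Per-trial :class:`~surrogateval.trial_data.EffectPair` data
        (at least four trials).
    within_corr
        Assumed within-study correlation between the two endpoints'
        estimation errors, in (-1, 1).  Published summaries do not
        identify it; 0 by default.
    """

    def __init__(self, effects: list[EffectPair], within_corr: float = 0.0):
        if len(effects) < 4:
            raise ValueError("insufficient trials for BRMA (need >= 4)")
        if not -1.0 < within_corr < 1.0:
            raise ValueError("within_corr must be in (-1, 1)")
        self.effects = list(effects)
        self.within_corr = float(within_corr)
        self._y, self._se = _as_arrays(self.effects)

    def fit(
        self,
        method: str = "reml",
        n_starts: int = 5,
        gtol: float = 1e-10,
        starts: list | None = None,
        polish: bool = True,
    ) -> BRMAResults:
        """Maximize the (restricted) marginal likelihood by multistart
        quasi-Newton optimization with a Nelder-Mead polish of the best
        candidate; ties broken by objective then by smallest parameter
        norm.  ``starts`` overrides the default start set (used e.g. to
        warm-start bootstrap refits)."""
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        reml = method == "reml"
        y, se = self._y, self._se
        args = (y, se, self.within_corr, reml)
        bounds = [(np.log(_TAU_FLOOR), 2.0)] * 2 + [(-_Z_CAP, _Z_CAP)]

        if starts is None:
            starts = [_moment_start(y, se)]
            starts += [
                [-2.0, -2.0, 0.0],
                [-1.0, -1.0, 1.0],
                [-1.0, -2.5, -1.0],
                [-3.0, -3.0, 0.5],
                [-0.5, -1.5, 2.0],
            ]
            starts = starts[: max(n_starts, 2)]

        candidates = []
        for x0 in starts:
            res = optimize.minimize(
                _profile_nll, x0, args=args, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-14, "gtol": gtol, "maxiter": 500},
            )
            candidates.append((res.fun, np.linalg.norm(res.x), res.x,
                               bool(res.success)))
        candidates.sort(key=lambda c: (c[0], c[1]))
        if polish:
            fun0, _, x_best, ok0 = candidates[0]
            res2 = optimize.minimize(
                _profile_nll, x_best, args=args, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 3000},
            )
            if not res2.success:
                # a fresh simplex unsticks occasional line-search stalls
                res2b = optimize.minimize(
                    _profile_nll, res2.x, args=args, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 3000},
                )
                if res2b.fun <= res2.fun:
                    res2 = res2b
            # polish confirming the optimum counts as convergence even
            # when it cannot improve on the quasi-Newton value
            confirmed = res2.success and res2.fun <= fun0 + 1e-8 * (1 + abs(fun0))
            if res2.fun <= fun0:
                candidates.insert(0, (res2.fun, np.linalg.norm(res2.x), res2.x,
                                      bool(res2.success or ok0)))
            elif confirmed and not ok0:
                candidates[0] = (fun0, np.linalg.norm(x_best), x_best, True)
        fun, _, p, ok = candidates[0]
        if not np.isfinite(fun):
            raise RuntimeError("BRMA optimization failed from all starts")

        t1, t2 = float(np.exp(p[0])), float(np.exp(p[1]))
        rho = float(np.tanh(p[2]))
        mu = _gls_mean(p, y, se, self.within_corr)
        boundary = (
            abs(rho) > 1 - 1e-6
            or t1 <= _TAU_FLOOR * (1 + 1e-9)
            or t2 <= _TAU_FLOOR * (1 + 1e-9)
        )
        return BRMAResults(
            mu1=float(mu[0]),
            mu2=float(mu[1]),
            tau1=t1,
            tau2=t2,
            rho=rho,
            loglik=-fun,
            converged=ok,
            boundary=boundary,
            n_trials=len(self.effects),
            within_corr=self.within_corr,
            method=method,
            model=self,
        )


def _numerical_hessian(f, x0, eps: float = 1e-4) -> np.ndarray:
    k = len(x0)
    h = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            if not np.all(np.isfinite([fpp, fpm, fmp, fmm, f0])):
                return np.full((k, k), np.nan)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return h


# -- thin functional wrappers (spec-style operation names) -------------------

def fit_brma(
    effects: list[EffectPair], within_corr: float = 0.0, method: str = "reml"
) -> BRMAResults:
    return BivariateEffectsMeta(effects, within_corr=within_corr).fit(method=method)


def r2_interval(
    fit: BRMAResults,
    level: float = 0.95,
    method: str = "fisher_z",
    n_boot: int = 1000,
    seed: int | None = None,
) -> IntervalEstimate:
    return fit.r2_interval(level=level, method=method, n_boot=n_boot, seed=seed)


def implied_line(fit: BRMAResults) -> tuple[float, float]:
    return fit.implied_line()


def predict_new(
    fit: BRMAResults,
    y1_new: float,
    se1_new: float,
    se2_new: float = 0.0,
    level: float = 0.95,
    include_param_uncertainty: bool = False,
):
    return fit.predict_new(
        y1_new, se1_new, se2_new, level, include_param_uncertainty
    )
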