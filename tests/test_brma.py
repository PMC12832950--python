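"""BRMA estimation: limits, equivariance, oracles, prediction, intervals."""

import numpy as np
import pytest

from surrogateval import (
    BivariateEffectsMeta,
    EffectPair,
    SimulationParams,
    simulate_trials,
    to_effects,
)


def make_effects(y1, y2, se1, se2):
    y1, y2 = np.asarray(y1, float), np.asarray(y2, float)
    se1 = np.broadcast_to(np.asarray(se1, float), y1.shape)
    se2 = np.broadcast_to(np.asarray(se2, float), y1.shape)
    return [
        EffectPair(f"t{i}", y1[i], se1[i], y2[i], se2[i]) for i in range(len(y1))
    ]


def synthetic_effects(seed, n=10, r2=0.6, se=(0.05, 0.10)):
    """Interior-optimum synthetic data via the package generator."""
    tau1, slope = 0.4, 0.3
    resid = float(np.sqrt(slope**2 * tau1**2 * (1 - r2) / r2))
    params = SimulationParams(
        n_trials=n, tau1=tau1, slope_true=slope, resid_sd=resid,
        se1_range=se, se2_range=se, seed=seed,
    )
    return to_effects(simulate_trials(params))


def test_needs_at_least_four_trials():
    eff = make_effects([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], 0.1, 0.1)
    with pytest.raises(ValueError, match="insufficient trials"):
        BivariateEffectsMeta(eff)


def test_noiseless_collinear_limit_gives_perfect_correlation():
    y1 = np.array([-0.8, -0.5, -0.2, 0.1, 0.4])
    eff = make_effects(y1, 0.5 * y1 + 0.03, 1e-6, 1e-6)
    fit = BivariateEffectsMeta(eff).fit()
    assert fit.r2 == pytest.approx(1.0, abs=1e-4)
    assert abs(fit.rho - 1.0) < 1e-4
    icept, slope = fit.implied_line()
    assert slope == pytest.approx(0.5, abs=1e-3)
    assert icept == pytest.approx(0.03, abs=1e-3)


@pytest.mark.parametrize("method, ddof", [("reml", 1), ("ml", 0)])
def test_vanishing_within_error_recovers_sample_moments(method, ddof):
    """With within-study errors -> 0 the fit reduces to the sample mean and
    sample covariance of the pairs (n-1 denominator under REML, n under ML)."""
    rng = np.random.default_rng(3)
    y = rng.multivariate_normal([-0.3, -0.1], [[0.09, 0.04], [0.04, 0.05]], size=7)
    eff = make_effects(y[:, 0], y[:, 1], 1e-5, 1e-5)
    fit = BivariateEffectsMeta(eff).fit(method=method)
    cov = np.cov(y.T, ddof=ddof)
    assert fit.mu1 == pytest.approx(y[:, 0].mean(), abs=1e-4)
    assert fit.mu2 == pytest.approx(y[:, 1].mean(), abs=1e-4)
    assert fit.tau1**2 == pytest.approx(cov[0, 0], rel=1e-3)
    assert fit.tau2**2 == pytest.approx(cov[1, 1], rel=1e-3)
    assert fit.rho * fit.tau1 * fit.tau2 == pytest.approx(cov[0, 1], rel=1e-3)


def test_label_swap_equivariance():
    eff = synthetic_effects(seed=5)
    fit = BivariateEffectsMeta(eff).fit()
    flipped = [
        EffectPair(e.trial_id, -e.y1, e.se1, -e.y2, e.se2) for e in eff
    ]
    fit_f = BivariateEffectsMeta(flipped).fit()
    assert fit_f.mu1 == pytest.approx(-fit.mu1, abs=1e-6)
    assert fit_f.mu2 == pytest.approx(-fit.mu2, abs=1e-6)
    assert fit_f.tau1 == pytest.approx(fit.tau1, rel=1e-5)
    assert fit_f.tau2 == pytest.approx(fit.tau2, rel=1e-5)
    assert abs(fit_f.rho) == pytest.approx(abs(fit.rho), abs=1e-6)
    assert fit_f.r2 == pytest.approx(fit.r2, abs=1e-6)


def test_boundary_fit_is_flagged_not_raised(primary_effects):
    fit = BivariateEffectsMeta(primary_effects).fit()
    assert fit.converged
    assert fit.boundary
    assert fit.r2 == pytest.approx(1.0, abs=1e-6)


def test_reml_matches_independent_multivariate_reference(all_effects):
    """Cross-check against R metafor rma.mv (struct='UN', REML) on the
    packaged table; reference values computed once with metafor 4.8."""
    fit = BivariateEffectsMeta(all_effects).fit(method="reml")
    assert fit.tau1 == pytest.approx(0.4194584, abs=2e-5)
    assert fit.tau2 == pytest.approx(0.1292242, abs=2e-5)
    assert fit.mu1 == pytest.approx(-0.4102424, abs=2e-5)
    assert fit.mu2 == pytest.approx(-0.1575645, abs=2e-5)
    assert abs(fit.rho) == pytest.approx(1.0, abs=1e-6)


class TestPredictNew:
    def test_prediction_at_the_pooled_mean(self):
        eff = synthetic_effects(seed=9)
        fit = BivariateEffectsMeta(eff).fit()
        m, lo, hi = fit.predict_new(fit.mu1, 0.05, 0.05)
        assert m == pytest.approx(fit.mu2, abs=1e-12)
        assert lo < m < hi

    def test_perfect_surrogate_limit(self):
        y1 = np.array([-0.6, -0.4, -0.2, 0.0, 0.2])
        eff = make_effects(y1, y1 + 0.1, 1e-7, 1e-7)
        fit = BivariateEffectsMeta(eff).fit()
        m, lo, hi = fit.predict_new(0.5, 1e-7, 1e-7)
        # rho = 1, equal taus: prediction tracks the shift one-for-one
        assert m == pytest.approx(fit.mu2 + (0.5 - fit.mu1), abs=1e-3)
        assert hi - lo < 1e-2

    def test_matches_closed_form_bivariate_conditional(self, primary_effects):
        """Independent oracle: build the joint 2x2 observable covariance and
        condition with the textbook matrix formula via numpy.linalg."""
        fit = BivariateEffectsMeta(primary_effects).fit()
        e = primary_effects[4]
        joint = np.array(
            [
                [fit.tau1**2 + e.se1**2, fit.rho * fit.tau1 * fit.tau2],
                [fit.rho * fit.tau1 * fit.tau2, fit.tau2**2 + e.se2**2],
            ]
        )
        mean = np.array([fit.mu1, fit.mu2])
        m_oracle = mean[1] + joint[0, 1] / joint[0, 0] * (e.y1 - mean[0])
        v_oracle = joint[1, 1] - joint[0, 1] ** 2 / joint[0, 0]
        m, lo, hi = fit.predict_new(e.y1, e.se1, e.se2)
        assert m == pytest.approx(m_oracle, abs=1e-10)
        half = 1.9599639845400545 * np.sqrt(v_oracle)
        assert hi - m == pytest.approx(half, abs=1e-10)

    def test_matches_monte_carlo_conditional_simulation(self):
        """Windowed Monte-Carlo draw from the fitted joint law reproduces the
        conditional mean and interval to ~2 significant figures."""
        eff = synthetic_effects(seed=21, n=12, r2=0.7)
        fit = BivariateEffectsMeta(eff).fit()
        e = eff[0]
        rng = np.random.default_rng(42)
        n_draws = 400_000
        th1 = fit.mu1 + fit.tau1 * rng.standard_normal(n_draws)
        cond_sd = fit.tau2 * np.sqrt(max(1 - fit.rho**2, 0.0))
        th2 = (
            fit.mu2
            + fit.rho * fit.tau2 / fit.tau1 * (th1 - fit.mu1)
            + cond_sd * rng.standard_normal(n_draws)
        )
        y1 = th1 + e.se1 * rng.standard_normal(n_draws)
        y2 = th2 + e.se2 * rng.standard_normal(n_draws)
        window = np.abs(y1 - e.y1) < 0.01
        assert window.sum() > 3000
        m, lo, hi = fit.predict_new(e.y1, e.se1, e.se2)
        sel = y2[window]
        assert m == pytest.approx(sel.mean(), abs=0.02)
        q_lo, q_hi = np.quantile(sel, [0.025, 0.975])
        assert lo == pytest.approx(q_lo, abs=0.05)
        assert hi == pytest.approx(q_hi, abs=0.05)

    def test_param_uncertainty_widens_interval(self):
        eff = synthetic_effects(seed=13)
        fit = BivariateEffectsMeta(eff).fit()
        _, lo0, hi0 = fit.predict_new(-0.5, 0.08, 0.10)
        _, lo1, hi1 = fit.predict_new(
            -0.5, 0.08, 0.10, include_param_uncertainty=True
        )
        assert hi1 - lo1 >= hi0 - lo0


class TestR2Interval:
    def test_null_correlation_interval_contains_zero(self):
        rng = np.random.default_rng(11)
        n = 14
        y1 = rng.normal(0, 0.3, n)
        y2 = rng.normal(0, 0.3, n)  # independent: rho ~ 0
        fit = BivariateEffectsMeta(make_effects(y1, y2, 0.05, 0.05)).fit()
        ci = fit.r2_interval()
        assert ci.lower == pytest.approx(0.0, abs=1e-9)
        assert ci.lower <= fit.r2 <= ci.upper

    def test_bootstrap_is_bit_identical_under_seed(self, primary_effects):
        fit = BivariateEffectsMeta(primary_effects).fit()
        a = fit.r2_interval(method="parametric_bootstrap", n_boot=60, seed=123)
        b = fit.r2_interval(method="parametric_bootstrap", n_boot=60, seed=123)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        c = fit.r2_interval(method="parametric_bootstrap", n_boot=60, seed=124)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_fisher_z_interval_brackets_truth_in_interior_case(self):
        eff = synthetic_effects(seed=2, n=20, r2=0.6, se=(0.03, 0.06))
        fit = BivariateEffectsMeta(eff).fit()
        assert not fit.boundary
        ci = fit.r2_interval(method="fisher_z")
        assert 0.0 <= ci.lower <= fit.r2 <= ci.upper <= 1.0

    def test_fisher_z_coverage_at_moderate_information(self):
        """Monte-Carlo coverage of the 95% interval near nominal (true
        R^2 = 0.8, 10 trials, 300 replicates)."""
        tau1, slope = 0.4, 0.3
        resid = float(np.sqrt(slope**2 * tau1**2 * (1 - 0.8) / 0.8))
        covered = 0
        total = 0
        for rep in range(300):
            params = SimulationParams(
                n_trials=10, tau1=tau1, slope_true=slope, resid_sd=resid,
                se1_range=(0.02, 0.05), se2_range=(0.02, 0.05),
                seed=np.random.SeedSequence([1000, rep]),
            )
            eff = to_effects(simulate_trials(params))
            fit = BivariateEffectsMeta(eff).fit()
            try:
                ci = fit.r2_interval(n_boot=150, seed=rep)
            except RuntimeError:
                continue
            total += 1
            covered += ci.lower <= 0.8 <= ci.upper
        assert total > 250
        assert 0.88 <= covered / total <= 0.99
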