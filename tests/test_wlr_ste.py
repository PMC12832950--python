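"""Weighted regression, bands, surrogate threshold effect."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from surrogateval import EffectPair, SurrogateRegression


def make_effects(y1, y2, se1=0.1, se2=0.1):
    y1, y2 = np.asarray(y1, float), np.asarray(y2, float)
    se1 = np.broadcast_to(np.asarray(se1, float), y1.shape)
    se2 = np.broadcast_to(np.asarray(se2, float), y1.shape)
    return [EffectPair(f"t{i}", y1[i], se1[i], y2[i], se2[i])
            for i in range(len(y1))]


def test_exact_line_with_equal_weights():
    x = np.array([-1.0, 0.0, 1.0])
    fit = SurrogateRegression(make_effects(x, 2 * x + 1),
                              weight_scheme="equal").fit()
    assert fit.intercept == pytest.approx(1.0, abs=1e-12)
    assert fit.slope == pytest.approx(2.0, abs=1e-12)
    assert fit.r2_weighted == pytest.approx(1.0, abs=1e-12)
    # zero residual scale: the band degenerates to the line
    lo, hi = fit.prediction_interval(0.3, band="confidence")
    assert lo == pytest.approx(hi, abs=1e-12)
    assert lo == pytest.approx(fit.predict(0.3), abs=1e-12)


def test_matches_statsmodels_wls(primary_effects):
    """Independent oracle: statsmodels WLS with the same weights."""
    fit = SurrogateRegression(primary_effects).fit()
    y1 = np.array([e.y1 for e in primary_effects])
    y2 = np.array([e.y2 for e in primary_effects])
    w = 1.0 / np.array([e.se2 for e in primary_effects]) ** 2
    sm_fit = sm.WLS(y2, sm.add_constant(y1), weights=w).fit()
    assert fit.intercept == pytest.approx(sm_fit.params[0], abs=1e-10)
    assert fit.slope == pytest.approx(sm_fit.params[1], abs=1e-10)
    assert fit.r2_weighted == pytest.approx(sm_fit.rsquared, abs=1e-10)
    assert fit.residual_scale == pytest.approx(sm_fit.mse_resid, rel=1e-10)


def test_equal_weights_equal_ols():
    rng = np.random.default_rng(5)
    x = rng.normal(size=12)
    y = 0.4 * x - 0.1 + rng.normal(0, 0.2, 12)
    fit = SurrogateRegression(make_effects(x, y), weight_scheme="equal").fit()
    b, a = np.polyfit(x, y, 1)
    assert fit.slope == pytest.approx(b, abs=1e-10)
    assert fit.intercept == pytest.approx(a, abs=1e-10)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_weighted_r2_identities(seed):
    """Squared weighted Pearson correlation == weighted coefficient of
    determination (asserted internally), and r2 stays in [0, 1]."""
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 12)
    x = rng.normal(size=n)
    if np.ptp(x) < 1e-6:
        x = x + np.linspace(0, 1, n)
    y = rng.normal(size=n)
    se2 = rng.uniform(0.05, 0.4, n)
    fit = SurrogateRegression(make_effects(x, y, 0.1, se2)).fit()
    assert 0.0 <= fit.r2_weighted <= 1.0


def test_degenerate_design_raises():
    with pytest.raises(ValueError, match="degenerate design"):
        SurrogateRegression(make_effects([0.2, 0.2, 0.2, 0.2],
                                         [0.1, 0.2, 0.3, 0.4])).fit()


def test_attenuation_correction_inflates_slope(primary_effects):
    plain = SurrogateRegression(primary_effects,
                                weight_scheme="inv_var_sum").fit()
    corrected = SurrogateRegression(
        primary_effects, weight_scheme="inv_var_sum",
        attenuation_correction=True,
    ).fit()
    assert corrected.slope > plain.slope
    # closed-form check of the corrected slope
    y1 = np.array([e.y1 for e in primary_effects])
    y2 = np.array([e.y2 for e in primary_effects])
    se1 = np.array([e.se1 for e in primary_effects])
    w = 1.0 / (se1**2 + np.array([e.se2 for e in primary_effects]) ** 2)
    sw = w.sum()
    xb, yb = (w * y1).sum() / sw, (w * y2).sum() / sw
    sxy = (w * (y1 - xb) * (y2 - yb)).sum() / sw
    sxx = (w * (y1 - xb) ** 2).sum() / sw
    me = (w * se1**2).sum() / sw
    assert corrected.slope == pytest.approx(sxy / (sxx - me), rel=1e-12)


class TestSte:
    def test_consistency_with_band(self, primary_effects):
        """Upper band limit vanishes at the reported threshold (1e-8)."""
        fit = SurrogateRegression(primary_effects).fit()
        for band in ("confidence", "prediction"):
            ste = fit.compute_ste(band=band)
            if not ste.solvable:
                continue
            _, hi = fit.prediction_interval(ste.x_threshold, band=band)
            assert abs(hi) < 1e-8

    def test_monotone_in_residual_scatter(self, primary_effects):
        fit = SurrogateRegression(primary_effects).fit()
        ste0 = fit.compute_ste()
        inflated = dataclasses.replace(
            fit, residual_scale=fit.residual_scale * 2.0, model=fit.model
        )
        ste1 = inflated.compute_ste()
        assert ste1.solvable
        assert ste1.ste_hr < ste0.ste_hr

    def test_nonpositive_slope_unsolvable(self):
        x = np.array([-0.5, -0.2, 0.1, 0.4])
        fit = SurrogateRegression(make_effects(x, -0.5 * x)).fit()
        ste = fit.compute_ste()
        assert not ste.solvable
        assert ste.ste_hr is None

    def test_noiseless_limit_crosses_beyond_null(self):
        """With negligible scatter around a line with negative intercept the
        threshold solves the line itself: x = 0.032/0.332, STE ~ 1.10 > 1,
        reported as solvable with the exceeds-null flag."""
        x = np.linspace(-1.2, 0.2, 6)
        y = -0.032 + 0.332 * x + 1e-9 * np.sin(np.arange(6))
        fit = SurrogateRegression(make_effects(x, y), weight_scheme="equal").fit()
        ste = fit.compute_ste()
        assert ste.solvable and ste.exceeds_null
        assert ste.ste_hr == pytest.approx(np.exp(0.032 / 0.332), abs=1e-3)

    def test_band_never_crossing_is_unsolvable(self):
        rng = np.random.default_rng(8)
        x = rng.normal(-0.4, 0.3, 6)
        y = 0.05 * x + rng.normal(0, 1.5, 6)  # huge scatter, tiny slope
        fit = SurrogateRegression(make_effects(x, y, 0.1, 0.5)).fit()
        ste = fit.compute_ste()
        if fit.slope > 0:
            assert not ste.solvable or ste.exceeds_null


class TestR2Interval:
    def test_fisher_z_needs_four_trials(self):
        fit = SurrogateRegression(
            make_effects([-0.3, 0.0, 0.3], [-0.1, 0.0, 0.1])
        ).fit()
        with pytest.raises(ValueError, match=">= 4"):
            fit.r2_interval()

    def test_perfect_collinearity_point_is_one(self):
        x = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])
        fit = SurrogateRegression(make_effects(x, 0.5 * x - 0.1)).fit()
        assert fit.r2_weighted == pytest.approx(1.0, abs=1e-12)

    def test_bootstrap_deterministic_under_seed(self, primary_effects):
        fit = SurrogateRegression(primary_effects).fit()
        a = fit.r2_interval(method="bootstrap", n_boot=200, seed=7)
        b = fit.r2_interval(method="bootstrap", n_boot=200, seed=7)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_bootstrap_coverage_at_least_85_percent(self):
        """Trial-resampling bootstrap interval covers the generating weighted
        correlation in at least 85% of 200 synthetic replicates (n = 10,
        true R^2 ~ 0.65)."""
        rho2 = 0.65
        slope, sx = 0.5, 0.4
        resid = np.sqrt(slope**2 * sx**2 * (1 - rho2) / rho2)
        covered = 0
        for rep in range(200):
            rng = np.random.default_rng(np.random.SeedSequence([77, rep]))
            x = rng.normal(-0.4, sx, 10)
            y = -0.05 + slope * x + rng.normal(0, resid, 10)
            fit = SurrogateRegression(
                make_effects(x, y, 0.05, rng.uniform(0.05, 0.15, 10))
            ).fit()
            ci = fit.r2_interval(method="bootstrap", n_boot=300, seed=rep)
            covered += ci.lower <= rho2 <= ci.upper
        assert covered / 200 >= 0.85
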