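"""Weibull fitting, criteria extraction and the nonparametric stage."""

import numpy as np
import pytest

from aromaflux.curves import (
    descending_threshold_crossing,
    weibull_ascending,
    weibull_ascending_deriv,
    weibull_descending,
)
from aromaflux.kinetics import (
    aa_consumption_criteria,
    biomass_criteria,
    extract_production_criteria,
    fit_weibull_ascending,
    fit_weibull_descending,
    mu_max,
    point_aa0,
    specific_rate,
    sugar_axis_from_co2,
)
from aromaflux.smoothing import smooth_production


class TestSugarAxis:
    @pytest.mark.parametrize("co2, sugar", [(0.0, 0.0), (88.0, 180.0), (35.0, 71.590909)])
    def test_stoichiometric_factor(self, co2, sugar):
        assert sugar_axis_from_co2(np.array([co2]))[0] == pytest.approx(sugar, rel=1e-6)

    def test_clipped_to_initial_sugar(self):
        out = sugar_axis_from_co2(np.array([0.0, 88.0, 100.0]), initial_sugar=180.0)
        assert out[-1] == 180.0

    def test_decreasing_channel_rejected(self):
        with pytest.raises(ValueError):
            sugar_axis_from_co2(np.array([0.0, 5.0, 4.0]))


class TestWeibullFits:
    @pytest.mark.parametrize(
        "variant, params",
        [("ascending", (2.0, 1.0, 100.0, 50.0)), ("descending", (3.0, 0.0, 100.0, 40.0))],
    )
    def test_noiseless_self_consistency(self, variant, params):
        x = np.linspace(0.5, 150, 80)
        f = weibull_ascending if variant == "ascending" else weibull_descending
        y = f(x, *params)
        fit = (fit_weibull_ascending if variant == "ascending" else fit_weibull_descending)(x, y)
        assert fit.converged
        for got, want in zip((fit.b, fit.c, fit.d, fit.e), params):
            assert got == pytest.approx(want, rel=1e-5, abs=1e-5)

    def test_value_at_inflection_ascending(self):
        fit = fit_weibull_ascending(
            np.linspace(0.5, 150, 60), weibull_ascending(np.linspace(0.5, 150, 60), 2, 1, 100, 50)
        )
        assert fit(fit.e) == pytest.approx(fit.c + (fit.d - fit.c) * (1 - np.exp(-1)), rel=1e-6)

    def test_value_at_inflection_descending(self):
        x = np.linspace(0.5, 120, 60)
        fit = fit_weibull_descending(x, weibull_descending(x, 3, 0, 100, 40))
        assert fit(fit.e) == pytest.approx(fit.c + (fit.d - fit.c) * np.exp(-1), rel=1e-6)

    def test_variant_duality(self):
        # fitting (x, d + c - y) with the other variant returns the same (b, e)
        x = np.linspace(0.5, 120, 60)
        b, c, d, e = 2.5, 5.0, 90.0, 35.0
        y = weibull_ascending(x, b, c, d, e)
        fit = fit_weibull_descending(x, d + c - y)
        assert fit.b == pytest.approx(b, rel=1e-5)
        assert fit.e == pytest.approx(e, rel=1e-5)

    def test_noisy_recovery_unbiased(self):
        # multiplicative noise at the duplicate-reproducibility level,
        # on the default generator's biomass conditions and sampling grid
        true = (2.5, 1.0, 150.0, 25.0)
        x = np.arange(0.25, 120, 0.25)
        yt = weibull_ascending(x, *true)
        est = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            fit = fit_weibull_ascending(x, yt * (1 + rng.normal(0, 0.03, x.size)))
            est.append([fit.b, fit.c, fit.d, fit.e])
        bias = np.mean(est, axis=0) / np.array(true) - 1
        assert np.all(np.abs(bias) < 0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull_ascending(np.arange(1, 5.0), np.arange(1, 5.0))


class TestBiomassCriteria:
    def test_mu_max_matches_brute_force_grid(self):
        params = (2.0, 1.0, 100.0, 50.0)
        t = np.linspace(1, 150, 100)
        fit = fit_weibull_ascending(t, weibull_ascending(t, *params))
        dense = np.linspace(1, 150, 40000)
        f = weibull_ascending(dense, *params)
        brute = np.max(np.gradient(f, dense) / f)
        assert mu_max(fit, t) == pytest.approx(brute, rel=1e-3)

    def test_constant_culture_has_no_growth(self):
        t = np.linspace(1, 100, 50)
        fit = fit_weibull_ascending(t, np.full(50, 80.0) + 1e-9 * t)
        assert mu_max(fit, t) == pytest.approx(0.0, abs=1e-6)

    def test_max_biomass_is_plateau_and_inflection_in_sugar(self):
        t = np.linspace(0.5, 150, 80)
        sugar = 180 * t / t[-1]
        fit = fit_weibull_ascending(t, weibull_ascending(t, 2, 1, 100, 50))
        crit = biomass_criteria(fit, t, sugar)
        assert crit.max_biomass == pytest.approx(fit.d)
        assert crit.inflection_point == pytest.approx(np.interp(fit.e, t, sugar))
        assert crit.mu_max > 0


class TestPointAA0:
    def test_closed_form_oracle(self):
        # symbolic inversion of exp(-exp(b ln(x/e))) = theta
        assert descending_threshold_crossing(3.0, 40.0, 0.01) == pytest.approx(
            40 * np.log(100) ** (1 / 3), rel=1e-12
        )
        x = np.linspace(0.5, 120, 60)
        fit = fit_weibull_descending(x, weibull_descending(x, 3, 0, 100, 40))
        # numeric oracle: root of exp(-(x/40)^3) = 0.01
        from scipy.optimize import brentq

        oracle = brentq(lambda v: np.exp(-((v / 40) ** 3)) - 0.01, 40, 120)
        assert point_aa0(fit, 0.01) == pytest.approx(oracle, rel=1e-3)

    def test_inflection_identity_threshold(self):
        # theta = 1/e makes the crossing land exactly at x = e
        x = np.linspace(0.5, 120, 60)
        fit = fit_weibull_descending(x, weibull_descending(x, 3, 0, 100, 40))
        assert point_aa0(fit, np.exp(-1.0)) == pytest.approx(fit.e, rel=1e-5)

    def test_high_floor_reports_not_exhausted(self):
        x = np.linspace(0.5, 120, 60)
        fit = fit_weibull_descending(x, weibull_descending(x, 3, 20, 100, 40))
        crit = aa_consumption_criteria(fit, x, threshold_frac=0.01)
        assert np.isnan(crit.point_aa0) and not crit.exhausted

    def test_wrong_variant_rejected(self):
        x = np.linspace(0.5, 120, 60)
        fit = fit_weibull_ascending(x, weibull_ascending(x, 2, 0, 100, 40))
        with pytest.raises(ValueError):
            point_aa0(fit)


class TestSmoothing:
    def test_noiseless_weibull_reproduced_with_derivative(self):
        p = (2.2, 0.0, 150.0, 45.0)
        x = np.linspace(1, 120, 120)
        sm = smooth_production(x, weibull_ascending(x, *p))
        interior = x[(x > 12) & (x < 108)]
        f = weibull_ascending(interior, *p)
        d = weibull_ascending_deriv(interior, *p)
        m = f > 0.01 * f.max()
        assert np.max(np.abs(sm.predict(interior)[m] - f[m]) / f[m]) < 0.01
        md = d > 0.1 * d.max()
        assert np.max(np.abs(sm.derivative(interior)[md] - d[md]) / d[md]) < 0.02

    def test_constant_series_has_zero_derivative(self):
        x = np.linspace(0, 10, 30)
        sm = smooth_production(x, np.full(30, 4.2))
        assert np.allclose(sm.derivative(x), 0.0, atol=1e-9)
        assert np.allclose(sm.predict(x), 4.2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_production(np.arange(5.0), np.arange(5.0))


class TestSpecificRate:
    def test_unit_identity_and_zero(self):
        assert specific_rate(np.array([1.0]), np.array([1.0]))[0] == 1.0
        assert np.all(specific_rate(np.zeros(5), np.full(5, 3.0)) == 0)

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            specific_rate(np.ones(3), np.array([1.0, 0.0, 2.0]))


class TestProductionCriteria:
    def _biomass_fit(self):
        t = np.arange(0.25, 120, 0.25)
        return fit_weibull_ascending(t, weibull_ascending(t, 2.5, 1.0, 150.0, 25.0))

    def test_recovers_truth_on_noiseless_synthetic_curve(self):
        prod = (3.5, 0.0, 150.0, 50.0)
        bio = (2.5, 1.0, 150.0, 25.0)
        t = np.linspace(1, 120, 120)
        sugar = 196 * t / t[-1]
        crit = extract_production_criteria(
            "x", t, weibull_ascending(t, *prod), sugar, self._biomass_fit()
        )
        dense = np.linspace(1, 120, 20000)
        q_true = weibull_ascending_deriv(dense, *prod) / weibull_ascending(dense, *bio)
        i = np.argmax(q_true)
        assert crit.max_production == pytest.approx(weibull_ascending(t[-1], *prod), rel=0.01)
        assert crit.srmax == pytest.approx(q_true[i], rel=0.03)
        assert crit.point_srmax == pytest.approx(np.interp(dense[i], t, sugar), rel=0.03)

    def test_monotone_linear_production_flags_boundary(self):
        t = np.linspace(1, 120, 60)
        sugar = 196 * t / t[-1]
        with pytest.warns(UserWarning, match="boundary"):
            crit = extract_production_criteria(
                "lin", t, 0.5 * t, sugar, self._biomass_fit()
            )
        assert crit.at_boundary

    def test_zero_production_compound(self):
        t = np.linspace(1, 120, 60)
        sugar = 196 * t / t[-1]
        crit = extract_production_criteria(
            "none", t, np.zeros(60), sugar, self._biomass_fit()
        )
        assert crit.max_production == pytest.approx(0.0, abs=1e-9)
        assert crit.srmax == pytest.approx(0.0, abs=1e-9)


class TestInvariances:
    def test_criteria_equivariant_under_sugar_rescaling(self):
        t = np.linspace(1, 120, 120)
        y = weibull_ascending(t, 3.5, 0.0, 150.0, 50.0)
        bio = TestProductionCriteria()._biomass_fit()
        sugar = 196 * t / t[-1]
        c1 = extract_production_criteria("x", t, y, sugar, bio)
        c2 = extract_production_criteria("x", t, y, 2 * sugar, bio)
        assert c2.point_srmax == pytest.approx(2 * c1.point_srmax, rel=1e-9)
        assert c2.srmax == pytest.approx(c1.srmax, rel=1e-9)
        assert c2.max_production == pytest.approx(c1.max_production, rel=1e-9)
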