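"""4PL curve behaviour, constrained fitting, IC50 CIs and fit flags."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platescreen.dose_response import (
    DilutionSeries,
    FitConstraints,
    FourPLParams,
    absolute_ic50,
    classify_fit,
    design_dilution,
    fit_4pl,
    four_pl,
    ic50_confidence,
    normalize_viability,
    replicate_spread,
)
from platescreen.errors import ConfigurationError, DegenerateDataError, InputError
from platescreen.synthetic import simulate_dose_response

TRUTH = FourPLParams(top=1.0, bottom=0.0, ic50=2.0, hill=1.5)
SERIES = design_dilution(100.0, factor=3, n_levels=8)


class TestCurve:
    def test_midpoint_identity(self):
        p = FourPLParams(top=0.9, bottom=0.1, ic50=3.0, hill=2.0)
        assert four_pl(3.0, p) == pytest.approx((0.9 + 0.1) / 2)

    def test_zero_dose_gives_top(self):
        assert four_pl(0.0, TRUTH) == pytest.approx(1.0)

    def test_hand_computed_point(self):
        p = FourPLParams(top=1.0, bottom=0.0, ic50=1.0, hill=1.0)
        assert four_pl(3.0, p) == pytest.approx(0.25)

    @given(
        st.floats(0.5, 1.2),   # top
        st.floats(0.0, 0.3),   # bottom
        st.floats(0.01, 50),   # ic50
        st.floats(0.2, 6),     # hill
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_decreasing_and_midpoint(self, top, bottom, ic50, hill):
        p = FourPLParams(top=top, bottom=bottom, ic50=ic50, hill=hill)
        c = np.geomspace(ic50 / 100, ic50 * 100, 40)
        v = four_pl(c, p)
        assert np.all(np.diff(v) < 0)
        assert four_pl(ic50, p) == pytest.approx((top + bottom) / 2, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InputError):
            four_pl(-1.0, TRUTH)


class TestDesign:
    def test_factor_three_series(self):
        expected = [100, 33.3333, 11.1111, 3.7037, 1.23457, 0.411523, 0.137174, 0.0457247]
        np.testing.assert_allclose(SERIES.concentrations, expected, rtol=1e-4)

    def test_strictly_decreasing_geometric(self):
        c = np.array(SERIES.concentrations)
        assert np.all(np.diff(c) < 0)
        np.testing.assert_allclose(c[:-1] / c[1:], 3.0, rtol=1e-12)

    def test_below_minimum_levels_warns(self):
        with pytest.warns(UserWarning):
            s = design_dilution(10.0, factor=2, n_levels=2)
        assert s.concentrations == (10.0, 5.0)

    def test_invalid_factor(self):
        with pytest.raises(ConfigurationError):
            design_dilution(10.0, factor=5, n_levels=8)

    def test_zero_top_conc(self):
        with pytest.raises(InputError):
            design_dilution(0.0, factor=2, n_levels=8)


class TestNormalizeViability:
    def test_fixed_points(self):
        controls = [10_000.0, 10_000.0]
        v = normalize_viability([10_000.0, 0.0, 2_000.0], controls)
        np.testing.assert_allclose(v, [1.0, 0.0, 0.2])

    def test_zero_control_mean_rejected(self):
        with pytest.raises(InputError):
            normalize_viability([1.0], [0.0, 0.0])

    def test_one_control_rejected(self):
        with pytest.raises(InputError):
            normalize_viability([1.0], [10_000.0])


class TestFit:
    def test_noiseless_recovery(self):
        obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.0, seed=0)
        fit = fit_4pl(obs["conc_um"], obs["viability"])
        assert fit.converged
        assert fit.params.ic50 == pytest.approx(TRUTH.ic50, rel=1e-6)
        assert fit.params.hill == pytest.approx(TRUTH.hill, rel=1e-6)
        assert fit.params.top == pytest.approx(TRUTH.top, abs=1e-6)
        assert abs(fit.params.bottom) < 1e-6

    def test_noiseless_ci_collapses(self):
        obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.0, seed=0)
        fit = fit_4pl(obs["conc_um"], obs["viability"])
        lo, hi = fit.ic50_ci95
        assert hi - lo < 1e-6

    def test_constraints_honored_exactly(self):
        obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.05, seed=11)
        fit = fit_4pl(
            obs["conc_um"], obs["viability"],
            FitConstraints(fix_bottom_zero=True, fix_top_one=True),
        )
        assert fit.params.bottom == 0.0
        assert fit.params.top == 1.0

    def test_constrained_rss_not_below_unconstrained(self):
        obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.05, seed=5)
        free = fit_4pl(obs["conc_um"], obs["viability"])
        constrained = fit_4pl(
            obs["conc_um"], obs["viability"], FitConstraints(fix_bottom_zero=True)
        )
        assert constrained.rss >= free.rss - 1e-12

    def test_refit_idempotent(self):
        obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.05, seed=3)
        fit = fit_4pl(obs["conc_um"], obs["viability"])
        refit = fit_4pl(obs["conc_um"], obs["viability"], start=fit.params)
        assert refit.params.ic50 == pytest.approx(fit.params.ic50, rel=1e-8)
        assert refit.params.hill == pytest.approx(fit.params.hill, rel=1e-8)

    def test_scale_equivariance(self):
        obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.05, seed=9)
        base = fit_4pl(obs["conc_um"], obs["viability"])
        k = 7.0
        scaled = fit_4pl(obs["conc_um"] * k, obs["viability"])
        assert scaled.params.ic50 == pytest.approx(k * base.params.ic50, rel=1e-6)
        assert scaled.params.hill == pytest.approx(base.params.hill, rel=1e-6)
        np.testing.assert_allclose(
            scaled.ic50_ci95, np.asarray(base.ic50_ci95) * k, rtol=1e-5
        )

    def test_flat_viability_is_degenerate(self):
        conc = np.repeat(SERIES.concentrations, 4)
        with pytest.raises(DegenerateDataError):
            fit_4pl(conc, np.ones_like(conc))

    def test_too_few_concentrations(self):
        with pytest.raises(InputError):
            fit_4pl([1.0, 2.0, 4.0], [1.0, 0.5, 0.1])

    def test_ci_contains_estimate(self):
        obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.05, seed=21)
        fit = fit_4pl(obs["conc_um"], obs["viability"])
        lo, hi = fit.ic50_ci95
        assert lo <= fit.params.ic50 <= hi

    def test_log10_ic50_bias_small(self):
        errors = []
        for seed in range(60):
            obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.05, seed=seed)
            fit = fit_4pl(obs["conc_um"], obs["viability"])
            errors.append(np.log10(fit.params.ic50 / TRUTH.ic50))
        assert abs(np.mean(errors)) < 0.05


class TestCIAndFlags:
    def test_confidence_level_widens_interval(self):
        obs = simulate_dose_response(TRUTH, SERIES, noise_sd=0.05, seed=2)
        fit = fit_4pl(obs["conc_um"], obs["viability"])
        lo95, hi95 = ic50_confidence(fit, 0.95)
        lo99, hi99 = ic50_confidence(fit, 0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_steep_slope_flag(self):
        fit = fit_4pl(
            *_obs(FourPLParams(top=1, bottom=0, ic50=1.0, hill=4.2))
        )
        assert "steep_slope" in classify_fit(fit)

    def test_incomplete_kill_flag(self):
        fit = fit_4pl(*_obs(FourPLParams(top=1, bottom=0.2, ic50=1.0, hill=1.0)))
        assert "incomplete_kill" in classify_fit(fit)

    def test_clean_fit_has_no_flags(self):
        fit = fit_4pl(*_obs(FourPLParams(top=1, bottom=0.0, ic50=1.0, hill=1.0)))
        assert classify_fit(fit) == set()

    def test_high_variability_flag(self):
        conc = np.repeat(SERIES.concentrations, 4)
        rng = np.random.default_rng(4)
        viab = four_pl(conc, TRUTH) + rng.normal(0, 0.3, conc.size)
        spread = replicate_spread(conc, viab)
        assert spread > 0.15
        fit = fit_4pl(conc, viab)
        assert "high_variability" in classify_fit(fit, spread=spread)

    def test_absolute_ic50(self):
        # top 1, bottom 0: absolute and relative IC50 coincide
        assert absolute_ic50(FourPLParams(1.0, 0.0, 2.0, 1.5)) == pytest.approx(2.0)
        # incomplete kill never reaches 50% viability from top 0.9, bottom 0.55
        assert np.isnan(absolute_ic50(FourPLParams(0.9, 0.55, 2.0, 1.0)))


def _obs(params, noise_sd=0.0, seed=0):
    obs = simulate_dose_response(params, SERIES, noise_sd=noise_sd, seed=seed)
    return obs["conc_um"].to_numpy(), obs["viability"].to_numpy()
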