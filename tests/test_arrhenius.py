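import math

import numpy as np
import pytest

from thermoramp.arrhenius import (
    ArrheniusFit,
    activation_parameters,
    apply_temperature_cutoffs,
    extrapolate_rate,
    eyring_delta_g,
    eyring_rate,
    weighted_arrhenius_fit,
    weighted_line_fit,
)
from thermoramp.constants import CONSTANTS
from thermoramp.errors import InsufficientDataError, ValidationError
from thermoramp.kinetics import MichaelisMentenFit

R = CONSTANTS.R_kcal


def mm_fit(temperature, kcat, kcat_se=1.0, converged=True, km=2e-4):
    return MichaelisMentenFit(
        temperature=temperature,
        kcat=kcat,
        kcat_se=kcat_se,
        km=km,
        km_se=1e-5,
        e0=1e-9,
        n_points=12,
        rss=1e-18,
        converged=converged,
    )


def fits_on_line(slope, intercept, temps, se=1.0):
    return [mm_fit(t, math.exp(intercept + slope / t), kcat_se=se) for t in temps]


TEMPS = np.linspace(281.0, 298.0, 8)


class TestCutoffs:
    def test_interval_filter(self):
        fits = fits_on_line(-7712.0, 32.06, np.arange(281.0, 299.0, 1.0))
        kept = apply_temperature_cutoffs(fits, 283.0, 296.0)
        temps = [f.temperature for f in kept]
        assert min(temps) >= 283.0 and max(temps) <= 296.0
        assert len(kept) == 14

    def test_wider_than_data_is_identity(self):
        fits = fits_on_line(-7712.0, 32.06, TEMPS)
        assert apply_temperature_cutoffs(fits, 200.0, 400.0) == fits

    def test_non_converged_fit_inside_range_removed(self):
        fits = fits_on_line(-7712.0, 32.06, TEMPS)
        fits[3] = mm_fit(fits[3].temperature, fits[3].kcat, converged=False)
        kept = apply_temperature_cutoffs(fits, 200.0, 400.0)
        assert len(kept) == len(fits) - 1

    def test_negative_parameter_fit_removed(self):
        fits = fits_on_line(-7712.0, 32.06, TEMPS)
        fits[0] = mm_fit(fits[0].temperature, -5.0)
        assert len(apply_temperature_cutoffs(fits, 200.0, 400.0)) == len(fits) - 1

    def test_too_few_survivors(self):
        fits = fits_on_line(-7712.0, 32.06, TEMPS)
        with pytest.raises(InsufficientDataError):
            apply_temperature_cutoffs(fits, 290.0, 291.0)


class TestWeightedFit:
    def test_noiseless_line_recovered_exactly(self):
        fit = weighted_arrhenius_fit(fits_on_line(-7712.0, 32.06, TEMPS))
        assert fit.slope == pytest.approx(-7712.0, rel=1e-10)
        assert fit.intercept == pytest.approx(32.06, rel=1e-10)

    def test_reproduces_hand_normal_equations(self):
        rng = np.random.default_rng(8)
        temps = TEMPS
        kcats = np.exp(32.06 - 7712.0 / temps) * (1 + rng.normal(0, 0.05, len(temps)))
        ses = kcats * rng.uniform(0.02, 0.2, len(temps))
        fit = weighted_arrhenius_fit([mm_fit(t, k, s) for t, k, s in zip(temps, kcats, ses)])
        # independent weighted normal equations
        x, y, w = 1.0 / temps, np.log(kcats), 1.0 / ses**2
        sw, sx, sy = w.sum(), (w * x).sum(), (w * y).sum()
        sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
        slope = (sw * sxy - sx * sy) / (sw * sxx - sx**2)
        intercept = (sy - slope * sx) / sw
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_two_point_interpolation_ignores_weights(self):
        x = np.array([1 / 280.0, 1 / 295.0])
        y = np.array([3.0, 5.0])
        for w in ([1.0, 1.0], [1e6, 1.0]):
            b, m, _, wrss = weighted_line_fit(x, y, np.asarray(w))
            assert b + m * x[0] == pytest.approx(y[0], rel=1e-12)
            assert b + m * x[1] == pytest.approx(y[1], rel=1e-12)

    def test_dominant_weight_pins_the_line(self):
        rng = np.random.default_rng(1)
        temps = TEMPS
        kcats = np.exp(32.06 - 7712.0 / temps) * (1 + rng.normal(0, 0.3, len(temps)))
        ses = np.full(len(temps), 1.0)
        ses[3] = 1e-3  # weight 1e6 times the others
        fit = weighted_arrhenius_fit([mm_fit(t, k, s) for t, k, s in zip(temps, kcats, ses)])
        pinned = fit.intercept + fit.slope / temps[3]
        assert abs(pinned - math.log(kcats[3])) < 1e-3

    def test_equal_weights_match_plain_ols(self):
        rng = np.random.default_rng(9)
        temps = TEMPS
        kcats = np.exp(32.06 - 7712.0 / temps) * (1 + rng.normal(0, 0.1, len(temps)))
        fit = weighted_arrhenius_fit([mm_fit(t, k, 5.0) for t, k in zip(temps, kcats)])
        coef = np.polyfit(1.0 / temps, np.log(kcats), 1)
        assert fit.slope == pytest.approx(coef[0], rel=1e-10)
        assert fit.intercept == pytest.approx(coef[1], rel=1e-10)

    def test_delta_log_weighting_available(self):
        fits = fits_on_line(-7712.0, 32.06, TEMPS, se=2.0)
        paper = weighted_arrhenius_fit(fits, "paper")
        dlog = weighted_arrhenius_fit(fits, "delta-log")
        # same noiseless line either way, different weights recorded
        assert dlog.slope == pytest.approx(paper.slope, rel=1e-9)
        assert not np.allclose(dlog.points["weight"], paper.points["weight"])

    def test_non_positive_kcat_rejected(self):
        fits = fits_on_line(-7712.0, 32.06, TEMPS)
        bad = fits[:-1] + [mm_fit(298.0, 0.0)]
        with pytest.raises(ValidationError, match="positive"):
            weighted_arrhenius_fit(bad)


class TestActivationParameters:
    def test_published_lipase_line(self):
        """The global regression line of the cold-active lipase gives its Ea/dG/dH/TdS."""
        act = activation_parameters(ArrheniusFit.from_line(-7712.0, 32.06), t_ref=287.5)
        assert act.ea == pytest.approx(15.325, abs=5e-3)
        assert act.delta_g == pytest.approx(13.82, abs=5e-3)
        assert act.delta_h == pytest.approx(14.75, abs=5e-3)
        assert act.t_delta_s == pytest.approx(0.94, abs=5e-3)
        assert act.kcat_ref == pytest.approx(math.exp(32.06 - 7712.0 / 287.5), rel=1e-12)

    def test_zero_slope_limit(self):
        act = activation_parameters(ArrheniusFit.from_line(0.0, 5.0), t_ref=300.0)
        assert act.ea == 0.0
        assert act.delta_h == pytest.approx(-R * 300.0, rel=1e-12)

    def test_eyring_identity_gives_zero_barrier(self):
        t = 300.0
        k_attempt = CONSTANTS.kB * t / CONSTANTS.h
        intercept = math.log(k_attempt)
        act = activation_parameters(ArrheniusFit.from_line(0.0, intercept), t_ref=t)
        assert act.delta_g == pytest.approx(0.0, abs=1e-10)
        assert eyring_delta_g(k_attempt, t) == pytest.approx(0.0, abs=1e-10)

    def test_thermodynamic_identities_hold_exactly(self):
        fit = weighted_arrhenius_fit(fits_on_line(-7712.0, 32.06, TEMPS, se=0.5))
        for t_ref in (280.0, 287.5, 298.0, 350.0):
            act = activation_parameters(fit, t_ref=t_ref)
            assert act.delta_h == pytest.approx(act.ea - R * t_ref, abs=1e-14)
            assert act.t_delta_s == pytest.approx(act.delta_h - act.delta_g, abs=1e-12)

    def test_ea_invariant_and_dh_linear_in_tref(self):
        fit = ArrheniusFit.from_line(-7712.0, 32.06)
        a1 = activation_parameters(fit, t_ref=285.0)
        a2 = activation_parameters(fit, t_ref=295.0)
        assert a1.ea == a2.ea
        assert (a2.delta_h - a1.delta_h) / 10.0 == pytest.approx(-R, rel=1e-12)

    def test_default_tref_is_mean_bin_temperature(self):
        fit = weighted_arrhenius_fit(fits_on_line(-7712.0, 32.06, TEMPS))
        act = activation_parameters(fit)
        assert act.t_ref == pytest.approx(TEMPS.mean())

    def test_standard_errors_propagate_from_covariance(self):
        rng = np.random.default_rng(12)
        temps = TEMPS
        kcats = np.exp(32.06 - 7712.0 / temps) * (1 + rng.normal(0, 0.1, len(temps)))
        fit = weighted_arrhenius_fit([mm_fit(t, k, 0.1 * k) for t, k in zip(temps, kcats)])
        act = activation_parameters(fit, t_ref=287.5)
        assert act.ea_se == pytest.approx(R * fit.slope_se, rel=1e-12)
        assert act.delta_h_se == act.ea_se
        assert act.t_delta_s_se == pytest.approx(R * 287.5 * fit.intercept_se, rel=1e-12)
        lo, hi = act.confidence_interval("ea")
        from scipy import stats

        tcrit = stats.t.ppf(0.975, fit.n_points - 2)
        assert hi - lo == pytest.approx(2 * tcrit * act.ea_se, rel=1e-10)

    def test_eyring_extrapolation_between_temperatures(self):
        # consistency: dG reconstructed from (dH, TdS) at t_ref reproduces the rate there
        dg = 16.0
        t_ref = 290.0
        k_ref = eyring_rate(dg, t_ref)
        dh = 17.0
        tds = dh - dg
        assert extrapolate_rate(dh, tds, t_ref, t_ref) == pytest.approx(k_ref, rel=1e-12)
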