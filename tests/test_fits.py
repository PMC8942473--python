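import numpy as np
import pytest

from sgnmech import models
from sgnmech.fits import (FitError, fit_biexp, fit_boltzmann,
                          fit_dose_response, fit_iv)
from sgnmech.synthetic import DEFAULT_GRIDS, gen_curve_data

BOLTZ_TRUE = dict(x_half=0.42, slope=8.0)
DOSE_TRUE = dict(i_initial=420.0, i_final=0.0, c_half=0.9, hill_p=1.0)
BIEXP_TRUE = dict(a1=250.0, tau1=3.6, a2=120.0, tau2=24.0, a_ss=60.0)
IV_TRUE = dict(conductance=3.2, e_rev=-1.4)


class TestBoltzmann:
    def test_noiseless_recovery(self):
        tab = gen_curve_data("boltzmann1", BOLTZ_TRUE)
        fit = fit_boltzmann(tab)
        assert fit.x_half == pytest.approx(0.42, rel=1e-6)
        assert fit.slope_s == pytest.approx(8.0, rel=1e-6)

    def test_midpoint_evaluates_to_half(self):
        fit = fit_boltzmann(gen_curve_data("boltzmann1", BOLTZ_TRUE))
        assert fit.predict(fit.x_half) == pytest.approx(0.5, abs=1e-9)

    def test_gating_force_scales_with_temperature(self):
        tab = gen_curve_data("boltzmann1", BOLTZ_TRUE)
        cold = fit_boltzmann(tab, temperature=280.0)
        warm = fit_boltzmann(tab, temperature=310.0)
        assert warm.z / cold.z == pytest.approx(310.0 / 280.0)

    def test_noisy_recovery_median_error(self):
        errs = []
        for seed in range(40):
            tab = gen_curve_data("boltzmann1", BOLTZ_TRUE,
                                 x=np.arange(0.0, 1.21, 0.12),
                                 noise_sd=0.02, seed=seed)
            fit = fit_boltzmann(tab)
            errs.append(abs(fit.x_half - 0.42) / 0.42)
        assert np.median(errs) < 0.02

    def test_unit_rescaling_equivariance(self):
        tab = gen_curve_data("boltzmann1", BOLTZ_TRUE, noise_sd=0.01, seed=3)
        fit_um = fit_boltzmann(tab)
        tab_nm = tab.copy()
        tab_nm["x"] = tab_nm["x"] * 1000.0
        fit_nm = fit_boltzmann(tab_nm)
        assert fit_nm.x_half == pytest.approx(fit_um.x_half * 1000.0,
                                              rel=1e-4)
        assert fit_nm.slope_s == pytest.approx(fit_um.slope_s / 1000.0,
                                               rel=1e-4)

    def test_two_component_fit_recovers_mixture(self):
        comps = dict(components=[(0.3, 12.0, 0.6), (0.8, 10.0, 0.4)])
        tab = gen_curve_data("boltzmann2", comps,
                             x=np.arange(0.0, 1.51, 0.075))
        fit = fit_boltzmann(tab, n_components=2)
        got = sorted(fit.components)
        assert got[0][0] == pytest.approx(0.3, abs=0.02)
        assert got[1][0] == pytest.approx(0.8, abs=0.02)

    def test_weight_one_mixture_equals_single_term(self):
        x = np.linspace(0, 1.2, 30)
        single = models.boltzmann(x, 0.42, 8.0)
        mixture = models.boltzmann_mixture(x, [(0.42, 8.0, 1.0),
                                               (0.9, 3.0, 0.0)])
        assert np.allclose(single, mixture)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_boltzmann((np.array([0.1, 0.5, 0.9]),
                           np.array([0.1, 0.5, 0.9])))

    def test_out_of_range_probabilities_rejected(self):
        x = np.linspace(0, 1, 6)
        with pytest.raises(FitError):
            fit_boltzmann((x, np.array([0, 0.2, 0.4, 0.8, 1.0, 1.5])))


class TestDoseResponse:
    def test_noiseless_recovery(self):
        tab = gen_curve_data("dose", DOSE_TRUE)
        fit = fit_dose_response(tab)
        assert fit.c_half == pytest.approx(0.9, rel=1e-6)
        assert fit.hill_p == pytest.approx(1.0, rel=1e-4)

    def test_half_block_at_c_half(self):
        fit = fit_dose_response(gen_curve_data("dose", DOSE_TRUE))
        assert fit.block_fraction(fit.c_half) == pytest.approx(0.5, abs=1e-6)

    def test_block_at_one_micromolar_matches_closed_form(self):
        """IC50 = 0.9 uM, Hill 1, full block: ~52.6% reduction at 1 uM."""
        fit = fit_dose_response(gen_curve_data("dose", DOSE_TRUE))
        assert 100 * fit.block_fraction(1.0) == pytest.approx(
            100 * models.hill_block_fraction(1.0, 0.9), abs=1e-3)

    def test_noisy_recovery_median_error(self):
        errs_c, errs_p = [], []
        for seed in range(40):
            tab = gen_curve_data("dose", DOSE_TRUE, noise_sd=5.0, seed=seed)
            fit = fit_dose_response(tab)
            errs_c.append(abs(fit.c_half - 0.9) / 0.9)
            errs_p.append(abs(fit.hill_p - 1.0))
        assert np.median(errs_c) < 0.05
        assert np.median(errs_p) < 0.05

    def test_flat_responses_rejected(self):
        with pytest.raises(FitError):
            fit_dose_response((np.array([0.1, 0.3, 1.0, 3.0]),
                               np.full(4, 100.0)))


class TestBiExp:
    def test_noiseless_recovery(self):
        tab = gen_curve_data("biexp", BIEXP_TRUE)
        fit = fit_biexp((tab["x"].to_numpy(), tab["y"].to_numpy()))
        assert fit.tau1 == pytest.approx(3.6, rel=1e-3)
        assert fit.tau2 == pytest.approx(24.0, rel=1e-3)
        assert fit.a_ss == pytest.approx(60.0, rel=1e-3)

    def test_constant_trace_collapses_to_steady_state(self):
        t = np.arange(0, 50, 0.5)
        fit = fit_biexp((t, np.full_like(t, 42.0)))
        assert fit.a1 == 0.0 and fit.a2 == 0.0
        assert fit.a_ss == pytest.approx(42.0)

    def test_tau_collapse_falls_back_to_single_exponential(self):
        t = np.arange(0, 60, 0.1)
        y = models.biexp(t, 200.0, 5.0, 0.0, 1e9, 20.0)  # single exp
        with pytest.warns(RuntimeWarning):
            fit = fit_biexp((t, y))
        assert fit.note.startswith("single exponential")
        assert fit.a2 == 0.0
        assert fit.tau1 == pytest.approx(5.0, rel=1e-3)

    def test_noisy_recovery_median_error(self):
        errs1, errs2 = [], []
        for seed in range(30):
            tab = gen_curve_data("biexp", BIEXP_TRUE, noise_sd=12.0,
                                 seed=seed)
            fit = fit_biexp((tab["x"].to_numpy(), tab["y"].to_numpy()))
            errs1.append(abs(fit.tau1 - 3.6) / 3.6)
            errs2.append(abs(fit.tau2 - 24.0) / 24.0)
        assert np.median(errs1) < 0.10
        assert np.median(errs2) < 0.10

    def test_short_window_rejected(self):
        with pytest.raises(FitError):
            fit_biexp((np.arange(10.0), np.arange(10.0)))


class TestIV:
    def test_reference_line_recovered_exactly(self):
        v = DEFAULT_GRIDS["iv"]
        i = models.iv_line(v, 3.2, -1.4)
        fit = fit_iv((v, i))
        assert fit.conductance == pytest.approx(3.2, rel=1e-12)
        assert fit.e_rev == pytest.approx(-1.4, rel=1e-9)

    def test_symmetric_points(self):
        fit = fit_iv((np.array([-10.0, 0.0, 10.0]),
                      np.array([-10.0, 0.0, 10.0])))
        assert fit.conductance == pytest.approx(1.0)
        assert fit.e_rev == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = np.arange(-90.0, 91.0, 30.0)
            i = models.iv_line(v, 3.2, -1.4) + rng.normal(0, 10, v.size)
            fit = fit_iv((v, i))
            # independent closed-form least squares
            vm, im = v.mean(), i.mean()
            slope = np.sum((v - vm) * (i - im)) / np.sum((v - vm) ** 2)
            intercept = im - slope * vm
            assert fit.conductance == pytest.approx(slope, rel=1e-12)
            assert fit.e_rev == pytest.approx(-intercept / slope, rel=1e-9)

    def test_degenerate_voltages_rejected(self):
        with pytest.raises(FitError):
            fit_iv((np.array([10.0, 10.0, 10.0]), np.array([1.0, 2.0, 3.0])))

    def test_zero_slope_flagged(self):
        fit = fit_iv((np.array([-10.0, 0.0, 10.0]), np.zeros(3)))
        assert np.isnan(fit.e_rev) and "undefined" in fit.note


class TestOptimizerSanity:
    def test_fit_rss_never_exceeds_true_parameter_rss(self):
        """The optimum must be at least as good as the generating model."""
        wins = 0
        for seed in range(25):
            tab = gen_curve_data("boltzmann1", BOLTZ_TRUE,
                                 x=np.arange(0.0, 1.21, 0.12),
                                 noise_sd=0.02, seed=seed)
            fit = fit_boltzmann(tab)
            rss_true = float(np.sum((models.boltzmann(
                tab["x"], **BOLTZ_TRUE) - tab["y"]) ** 2))
            wins += fit.rss <= rss_true + 1e-12
        assert wins >= 24
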