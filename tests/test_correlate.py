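"""Correlation estimators and FCS/FCCS model fits."""

import numpy as np
import pytest

from smbridge.correlate import (CorrelationCurve, compute_correlation,
                                calibrate_optics, effective_volume, fcs_model,
                                fit_fccs, fit_fcs, n_ad_from_amplitudes,
                                _fccs_models)
from smbridge.errors import AmplitudeDegenerateError, EmptyInputError
from smbridge.simulate import OpticalConfig, SpeciesSpec, simulate_photon_stream
from smbridge.streams import PhotonStream

OPTICS = OpticalConfig(w0=0.3, z0=1.5)
BOX = (1.2, 1.2, 6.0)


def poisson_stream(rate, duration, seed, channel=0, gate=0):
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
    return times


class TestFcsModel:
    def test_zero_lag_amplitude(self):
        # 1/(pi^1.5 * 0.09 * 1.5 * 10)
        assert fcs_model(0.0, 10.0, 430.0, 0.3, 1.5) == \
            pytest.approx(0.1330, abs=5e-5)

    def test_lateral_half_decay(self):
        # with z0 >> w0 the lateral factor halves at tau = w0^2/(4D)
        tau_half = 0.3 ** 2 / (4 * 430.0)
        assert tau_half == pytest.approx(52.3e-6, abs=0.1e-6)
        g = fcs_model(np.array([0.0, tau_half]), 1.0, 430.0, 0.3, 3e3)
        assert g[1] / g[0] == pytest.approx(0.5, rel=1e-3)

    def test_vanishes_at_high_concentration(self):
        taus = np.logspace(-6, 0, 10)
        assert np.all(fcs_model(taus, 1e12, 100.0, 0.3, 1.5) < 1e-10)

    def test_strictly_decreasing(self):
        taus = np.logspace(-7, 1, 200)
        g = fcs_model(taus, 5.0, 85.0, 0.25, 1.2)
        assert np.all(np.diff(g) < 0)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            fcs_model(-1e-6, 1.0, 1.0, 0.3, 1.5)


class TestEstimator:
    def _two_channel_stream(self, seed=0, duration=30.0, rate=3000.0):
        t1 = poisson_stream(rate, duration, seed)
        t2 = poisson_stream(rate, duration, seed + 1)
        times = np.concatenate([t1, t2])
        chan = np.concatenate([np.zeros(len(t1), np.uint8),
                               np.ones(len(t2), np.uint8)])
        order = np.argsort(times)
        return PhotonStream(times[order], chan[order],
                            np.zeros(len(times), np.uint8), duration)

    def test_independent_streams_uncorrelated(self):
        st = self._two_channel_stream()
        curve = compute_correlation(st, ("D", None), ("A", None),
                                    lag_range=(1e-4, 1.0))
        assert curve.kind == "cross"
        z = np.abs(curve.G) / np.maximum(curve.se, 1e-9)
        assert (z > 3).mean() <= 0.02

    def test_multitau_matches_direct_oracle(self):
        st = self._two_channel_stream(seed=5, duration=20.0, rate=5000.0)
        mt = compute_correlation(st, ("D", None), lag_range=(1e-4, 1.0),
                                 scheme="multitau")
        dr = compute_correlation(st, ("D", None), lag_range=(1e-4, 1.0),
                                 scheme="direct")
        np.testing.assert_allclose(mt.lags, dr.lags)
        scale = np.max(np.abs(dr.G))
        np.testing.assert_allclose(mt.G, dr.G, atol=1e-6 * max(scale, 1e-3))

    def test_time_shift_invariance(self):
        # wrapping the whole record around by a fixed offset leaves the
        # autocorrelation unchanged up to edge-bin truncation
        sp = SpeciesSpec("donor_only", conc=6.65, D=50.0, eps=5e3)
        st = simulate_photon_stream([sp], OPTICS, duration=15.0, dt=4.5e-5,
                                    box=BOX, seed=13)
        base = 4.5e-5
        shift = 1000 * base
        t2 = np.sort((st.times + shift) % st.duration)
        shifted = PhotonStream(t2, np.zeros_like(st.channel),
                               np.zeros_like(st.gate), st.duration)
        c1 = compute_correlation(st, ("D", None), lag_range=(base, 0.5))
        c2 = compute_correlation(shifted, ("D", None), lag_range=(base, 0.5))
        n = min(len(c1), len(c2))
        assert c1.G[0] > 0.1  # meaningful amplitude for the comparison
        np.testing.assert_allclose(c1.G[:n], c2.G[:n], atol=0.01)

    def test_empty_selection(self):
        st = self._two_channel_stream(seed=9, duration=5.0)
        with pytest.raises(EmptyInputError):
            compute_correlation(st, ("D", "Aex"), lag_range=(1e-4, 1.0))

    def test_lag_range_validation(self):
        st = self._two_channel_stream(seed=9, duration=5.0)
        with pytest.raises(ValueError):
            compute_correlation(st, ("D", None), lag_range=(1e-4, 10.0))
        with pytest.raises(ValueError):
            compute_correlation(st, ("D", None), lag_range=(0.0, 1.0))


def model_curve(C, D, optics, lags=None, se_frac=1e-4):
    if lags is None:
        lags = np.logspace(-5.5, -0.5, 80)
    g = fcs_model(lags, C, D, optics.w0, optics.z0)
    se = np.full_like(g, se_frac * g[0])
    return CorrelationCurve(lags, g, se, kind="auto_D")


class TestFitFcs:
    def test_noiseless_self_consistency(self):
        curve = model_curve(2.0, 430.0, OPTICS)
        fit = fit_fcs(curve, OPTICS)
        assert fit.C == pytest.approx(2.0, rel=1e-6)
        assert fit.D == pytest.approx(430.0, rel=1e-6)

    def test_refit_is_fixed_point(self):
        curve = model_curve(5.0, 60.0, OPTICS)
        fit1 = fit_fcs(curve, OPTICS)
        fit2 = fit_fcs(curve, OPTICS, init=fit1)
        assert fit2.C == pytest.approx(fit1.C, rel=1e-8)
        assert fit2.D == pytest.approx(fit1.D, rel=1e-8)

    def test_pure_background_amplitude_degenerate(self):
        lags = np.logspace(-5, -0.5, 40)
        rng = np.random.default_rng(0)
        curve = CorrelationCurve(lags, rng.normal(0, 1e-4, 40),
                                 np.full(40, 1e-4))
        with pytest.raises(AmplitudeDegenerateError):
            fit_fcs(curve, OPTICS)

    def test_amplitude_law_concentration_ratios(self):
        # fitted C at relative concentrations (1, 2, 4) recovers the ratios
        fits = []
        for i, conc in enumerate((3.325, 6.65, 13.3)):
            sp = SpeciesSpec("donor_only", conc=conc, D=50.0, eps=2e4)
            st = simulate_photon_stream([sp], OPTICS, duration=20.0,
                                        dt=4.5e-5, box=BOX, seed=31 + i)
            curve = compute_correlation(st, ("D", "Dex"),
                                        lag_range=(4.5e-5, 2.0))
            fits.append(fit_fcs(curve, OPTICS).C)
        assert fits[1] / fits[0] == pytest.approx(2.0, rel=0.15)
        assert fits[2] / fits[0] == pytest.approx(4.0, rel=0.15)

    def test_brightness_invariance(self):
        # doubling eps at fixed C leaves fitted C and D unchanged
        fits = []
        for i, eps in enumerate((1.5e4, 3e4)):
            sp = SpeciesSpec("donor_only", conc=6.65, D=50.0, eps=eps)
            st = simulate_photon_stream([sp], OPTICS, duration=20.0,
                                        dt=4.5e-5, box=BOX, seed=41 + i)
            curve = compute_correlation(st, ("D", "Dex"),
                                        lag_range=(4.5e-5, 2.0))
            fits.append(fit_fcs(curve, OPTICS))
        assert fits[1].C == pytest.approx(fits[0].C, rel=0.15)
        assert fits[1].D == pytest.approx(fits[0].D, rel=0.2)

    def test_cross_correlation_channel_order_symmetry(self):
        # for a stationary co-diffusing species G_DA(tau) = G_AD(tau)
        sp = SpeciesSpec("dual", conc=2.0, D=30.0, eps=3e4, efret=0.5)
        st = simulate_photon_stream([sp], OPTICS, duration=15.0, dt=1e-4,
                                    box=BOX, seed=51)
        g12 = compute_correlation(st, ("D", "Dex"), ("A", "Aex"),
                                  lag_range=(1e-4, 1.0))
        g21 = compute_correlation(st, ("A", "Aex"), ("D", "Dex"),
                                  lag_range=(1e-4, 1.0))
        sel = g12.G > 0.05 * g12.G[0]
        np.testing.assert_allclose(g12.G[sel], g21.G[sel], rtol=0.2,
                                   atol=0.01)

    def test_stream_recovery(self):
        # moderate-length acquisition; a sharper version runs in acceptance
        sp = SpeciesSpec("donor_only", conc=6.65, D=50.0, eps=5e3)
        st = simulate_photon_stream([sp], OPTICS, duration=30.0, dt=4.5e-5,
                                    box=BOX, seed=21)
        curve = compute_correlation(st, ("D", "Dex"), lag_range=(4.5e-5, 2.0))
        fit = fit_fcs(curve, OPTICS)
        c_eff = round(6.65 * np.prod(BOX)) / np.prod(BOX)
        assert fit.C == pytest.approx(c_eff, rel=0.15)
        assert fit.D == pytest.approx(50.0, rel=0.2)


class TestCalibration:
    def test_inverse_problem_recovers_waist(self):
        curve = model_curve(3.0, 430.0, OPTICS)
        optics = calibrate_optics(curve, D_ref=430.0)
        assert optics.w0 == pytest.approx(0.3, rel=0.01)
        assert optics.z0 == pytest.approx(1.5, rel=0.05)

    def test_dref_guard(self):
        curve = model_curve(3.0, 430.0, OPTICS)
        with pytest.raises(ValueError):
            calibrate_optics(curve, D_ref=0.0)

    def test_waist_scaling_law(self):
        # doubling the assumed D_ref scales the fitted waist by sqrt(2)
        curve = model_curve(3.0, 430.0, OPTICS)
        w1 = calibrate_optics(curve, D_ref=430.0, shape_ratio=5.0).w0
        w2 = calibrate_optics(curve, D_ref=860.0, shape_ratio=5.0).w0
        assert w2 / w1 == pytest.approx(np.sqrt(2), rel=1e-3)


class TestFccs:
    def test_printed_nad_arithmetic(self):
        assert n_ad_from_amplitudes(0.2, 1.0, 0.5) == pytest.approx(0.1414,
                                                                    abs=5e-5)

    def test_effective_volume(self):
        v = effective_volume(OPTICS)
        assert v == pytest.approx(np.pi ** 1.5 * 0.09 * 1.5 / (2 * np.sqrt(2)),
                                  rel=1e-12)

    def _model_curves(self, Ca, Cd, Cad, Da, Dd, Dad, noise=0.0, seed=0):
        lags = np.logspace(-5.5, -0.5, 70)
        p = dict(Ca=Ca, Cd=Cd, Cad=Cad, Da=Da, Dd=Dd, Dad=Dad)
        ga, gd, gx = _fccs_models(p, lags, OPTICS.w0, OPTICS.z0)
        rng = np.random.default_rng(seed)
        se = np.full_like(lags, max(noise, 1e-4 * ga[0]))
        curves = []
        for g, kind in ((ga, "auto_A"), (gd, "auto_D"), (gx, "cross")):
            gg = g + rng.normal(0, noise, g.size) if noise else g
            curves.append(CorrelationCurve(lags, gg, se, kind=kind))
        return curves

    def test_recovers_dual_fraction_and_slow_complex(self):
        ga, gd, gx = self._model_curves(1.4, 1.4, 0.6, 100, 100, 30,
                                        noise=2e-4, seed=3)
        fit = fit_fccs(ga, gd, gx, OPTICS)
        assert fit.Cad / (fit.Cd + fit.Cad) == pytest.approx(0.3, rel=0.15)
        assert fit.Dad < fit.Dd
        assert fit.significant

    def test_zero_cross_correlation_flagged_not_error(self):
        ga, gd, gx = self._model_curves(2.0, 2.0, 0.0, 100, 100, 30,
                                        noise=3e-4, seed=4)
        fit = fit_fccs(ga, gd, gx, OPTICS)
        assert not fit.significant
        assert abs(fit.n_ad) < 0.1 * 1 / (np.pi ** 1.5 * 0.09 * 1.5 * 2.0)

    def test_nad_consistency_with_amplitudes(self):
        ga, gd, gx = self._model_curves(1.0, 0.8, 0.4, 120, 90, 25)
        fit = fit_fccs(ga, gd, gx, OPTICS)
        pref = np.pi ** 1.5 * OPTICS.w0 ** 2 * OPTICS.z0
        ga0 = 1 / (pref * (fit.Ca + fit.Cad))
        gd0 = 1 / (pref * (fit.Cd + fit.Cad))
        gx0 = fit.Cad / (pref * (fit.Ca + fit.Cad) * (fit.Cd + fit.Cad))
        assert fit.n_ad == pytest.approx(n_ad_from_amplitudes(gx0, ga0, gd0),
                                         rel=1e-9)
        # the printed N_ad and the algebraic C_ad*V_eff differ by 2*sqrt(2)
        assert fit.n_ad_unscaled == pytest.approx(
            fit.n_ad * 2 * np.sqrt(2), rel=1e-9)

    def test_incompatible_lag_grids(self):
        ga, gd, gx = self._model_curves(1.0, 1.0, 0.2, 100, 100, 30)
        bad = CorrelationCurve(gx.lags * 1.5, gx.G, gx.se, kind="cross")
        with pytest.raises(ValueError):
            fit_fccs(ga, gd, bad, OPTICS)
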