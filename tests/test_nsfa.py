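"""Variance-mean construction and parabola inversion (NSFA)."""

import numpy as np
import pytest

from ampar_kinetics import (
    ChannelParams,
    NoiseModel,
    TraceEnsemble,
    VarianceCurve,
    build_scheme,
    fit_nsfa,
    make_stimulus,
    mean_occupancy,
    simulate_ensemble,
    variance_mean,
)


def _curve(mean, variance, sigma0=0.0, peak=None, vh=-70.0):
    mean = np.asarray(mean, float)
    variance = np.asarray(variance, float)
    return VarianceCurve(
        mean=mean, variance=variance, weights=np.ones_like(mean),
        sigma0_sq=sigma0, estimator="ensemble",
        bin_counts=np.ones(mean.size, int),
        peak_mean=peak if peak is not None else mean.max(), vh=vh, vr=0.0,
    )


class TestFitNsfa:
    def test_exact_parabola_inversion(self):
        x = np.linspace(1.0, 30.0, 12)
        y = 1.2 * x - x**2 / 50.0
        res = fit_nsfa(_curve(x, y))
        assert res.i == pytest.approx(1.2, rel=1e-9)
        assert res.n == pytest.approx(50.0, rel=1e-9)
        assert abs(res.sigma0_sq) < 1e-9

    def test_gamma_from_unitary_current(self):
        # i = 1.176 pA at Vh = -70, Vr = 0  ->  gamma = 16.8 pS
        x = np.linspace(1.0, 37.0, 10)
        y = 1.176 * x - x**2 / 64.0
        res = fit_nsfa(_curve(x, y, vh=-70.0))
        assert res.gamma == pytest.approx(16.8, rel=1e-9)

    def test_popen_peak(self):
        # I_peak = 37.6 pA with i = 1.176, N = 64 -> Popen = 0.4996
        x = np.linspace(1.0, 37.6, 10)
        y = 1.176 * x - x**2 / 64.0
        res = fit_nsfa(_curve(x, y, peak=37.6))
        assert res.popen_peak == pytest.approx(0.4996, abs=2e-4)

    def test_flat_curve_flagged_failure(self):
        x = np.linspace(1.0, 30.0, 10)
        res = fit_nsfa(_curve(x, np.full(10, 4.0)))
        assert not res.ok
        assert np.isnan(res.i) and np.isnan(res.n)

    def test_background_fixed_mode(self):
        x = np.linspace(1.0, 30.0, 12)
        y = 1.2 * x - x**2 / 50.0 + 2.5
        res = fit_nsfa(_curve(x, y, sigma0=2.5), fix_background=True)
        assert res.i == pytest.approx(1.2, rel=1e-9)
        assert res.n == pytest.approx(50.0, rel=1e-9)
        assert res.sigma0_sq == 2.5

    def test_too_few_bins_rejected(self):
        x = np.linspace(1.0, 30.0, 4)
        with pytest.raises(ValueError):
            fit_nsfa(_curve(x, 1.2 * x))


class TestVarianceMean:
    def test_identical_sweeps_zero_variance(self):
        t = np.arange(0, 50, 0.01)
        y = -30 * np.exp(-np.maximum(t - 20.0, 0) / 2.0) * (t >= 20.0)
        ens = TraceEnsemble(0.01, np.tile(y, (25, 1)), {"onset": 20.0})
        with pytest.warns(UserWarning):
            curve = variance_mean(ens)
        assert np.all(np.abs(curve.variance) < 1e-20)
        assert curve.sigma0_sq == 0.0

    def test_too_few_sweeps_rejected(self):
        ens = TraceEnsemble(0.01, np.zeros((5, 100)), {"onset": 0.5})
        with pytest.raises(ValueError):
            variance_mean(ens)

    def test_binomial_ensemble_matches_analytic(self):
        # noise-free ensemble: variance must follow i^2 N p (1-p)
        sch = build_scheme("gof")
        stim = make_stimulus("deactivation", dt=0.01, tail=29.0)
        ch = ChannelParams(64, 16.8)
        ens = simulate_ensemble(sch, stim, ch, NoiseModel(), 400, seed=11)
        curve = variance_mean(ens, n_bins=8)
        i = abs(ch.unitary_current)
        p = curve.mean / (i * ch.n_channels)
        analytic = i**2 * ch.n_channels * p * (1 - p)
        # Monte-Carlo agreement: binned variance within 15% of the binomial law
        assert np.all(np.abs(curve.variance - analytic) / analytic.max() < 0.15)

    def test_successive_difference_robust_to_rundown(self):
        # slow multiplicative amplitude wander (mean ~1): successive sweep
        # differences cancel it, the plain across-sweep variance does not
        sch = build_scheme("gof")
        stim = make_stimulus("deactivation", dt=0.01, tail=29.0)
        ch = ChannelParams(256, 16.8)
        factors = 1.0 + 0.15 * np.sin(2 * np.pi * np.arange(150) / 75.0)
        clean = simulate_ensemble(sch, stim, ch, NoiseModel(), 150, seed=21)
        run = simulate_ensemble(
            sch, stim, ch, NoiseModel(rundown_factors=factors), 150, seed=21
        )
        ref = variance_mean(clean, estimator="ensemble")
        sd = variance_mean(run, estimator="successive_difference")
        plain = variance_mean(run, estimator="ensemble")
        scale = ref.variance.max()
        assert np.abs(sd.variance - ref.variance).max() / scale < 0.15
        assert plain.variance.max() > 1.5 * ref.variance.max()


class TestRecoverySmoke:
    def test_single_seed_recovery(self):
        sch = build_scheme("gof")
        stim = make_stimulus("deactivation", dt=0.01, tail=39.0)
        ch = ChannelParams(64, 16.8)
        ens = simulate_ensemble(sch, stim, ch, NoiseModel(baseline_sd=1.0), 200, seed=1)
        res = fit_nsfa(variance_mean(ens), fix_background=True)
        assert res.ok
        assert res.i == pytest.approx(abs(ch.unitary_current), rel=0.10)
        assert res.n == pytest.approx(64, rel=0.15)
        assert res.gamma == pytest.approx(16.8, rel=0.10)
        assert 0 < res.popen_peak <= 1.0
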