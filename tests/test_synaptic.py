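"""Event detection, averaging, charge transfer, PPR and NMDAR late component."""

import numpy as np
import pytest

from ampar_kinetics import (
    EventList,
    Recording,
    Sweep,
    SynapticGenParams,
    average_events,
    charge_transfer,
    detect_events,
    generate_eepsc_pair,
    generate_mepsc_recording,
    nmdar_amplitude,
    paired_pulse_ratio,
    score_detection,
    synaptic_kernel,
)
from ampar_kinetics.traces import average_sweeps


def _events(onsets, peaks=None, amps=None):
    onsets = np.asarray(onsets, float)
    return EventList(
        onsets,
        np.asarray(peaks, float) if peaks is not None else onsets + 0.5,
        np.asarray(amps, float) if amps is not None else np.full(onsets.size, 20.0),
    )


class TestDetectEvents:
    def test_flat_noise_no_events(self):
        params = SynapticGenParams(rate_hz=0.0, noise_sd=4.0, duration_ms=60_000.0)
        rec, _ = generate_mepsc_recording(params, seed=2)
        assert len(detect_events(rec, threshold_sd=4.0)) <= 1

    def test_high_snr_detection(self):
        params = SynapticGenParams(rate_hz=1.0, amp_mean=20.0, noise_sd=4.0,
                                   duration_ms=30_000.0)
        rec, truth = generate_mepsc_recording(params, seed=4)
        det = detect_events(rec)
        score = score_detection(det, truth, tolerance=2.0)
        assert score.precision >= 0.9
        assert score.recall >= 0.9

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            Recording(Sweep(0.1, np.zeros(100)))

    def test_bad_threshold_rejected(self):
        params = SynapticGenParams(rate_hz=0.0, duration_ms=2000.0)
        rec, _ = generate_mepsc_recording(params, seed=1)
        with pytest.raises(ValueError):
            detect_events(rec, threshold_sd=0.0)


class TestScoreDetection:
    def test_perfect_detection(self):
        truth = _events([100.0, 500.0, 900.0])
        s = score_detection(truth, truth, tolerance=2.0)
        assert s.precision == 1.0 and s.recall == 1.0

    def test_empty_detection_convention(self):
        truth = _events([100.0, 500.0])
        s = score_detection(_events([]), truth, tolerance=2.0)
        assert s.recall == 0.0
        assert s.precision == 1.0  # documented convention
        assert "no-detections" in s.flags

    def test_shifted_detections_within_tolerance(self):
        truth = _events([100.0, 500.0, 900.0])
        shifted = _events([101.0, 501.0, 901.0])
        s = score_detection(shifted, truth, tolerance=2.0)
        assert s.true_positives == 3

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            score_detection(_events([1.0]), _events([1.0]), tolerance=-1.0)


class TestAverageEvents:
    def _make_recording(self, onsets_ms, amp=25.0, dt=0.1, dur=5000.0, noise=0.0, seed=0):
        kernel = synaptic_kernel(dt, 0.3, ((1.0, 2.0),))
        n = int(dur / dt) + 1
        y = np.zeros(n)
        for t0 in onsets_ms:
            i0 = int(round(t0 / dt))
            y[i0 : i0 + kernel.size] -= amp * kernel[: max(0, min(kernel.size, n - i0))]
        if noise:
            y += np.random.default_rng(seed).normal(0, noise, n)
        return Recording(Sweep(dt, y)), kernel

    def test_identical_events_recover_kernel(self):
        onsets = [500.0, 1500.0, 2500.0, 3500.0]
        rec, kernel = self._make_recording(onsets)
        avg = average_events(rec, _events(onsets), window=(5.0, 15.0))
        n_pre = int(5.0 / 0.1)
        seg = -avg.samples[n_pre : n_pre + 100]
        np.testing.assert_allclose(seg, 25.0 * kernel[:100], atol=1e-9)
        assert avg.annotations["n_used"] == 4

    def test_noise_shrinks_with_event_count(self):
        onsets_few = list(np.arange(500.0, 500.0 + 10 * 250, 250.0))
        onsets_many = list(np.arange(500.0, 500.0 + 90 * 250, 250.0))
        rec_f, kernel = self._make_recording(onsets_few, dur=30_000, noise=4.0, seed=1)
        rec_m, _ = self._make_recording(onsets_many, dur=30_000, noise=4.0, seed=1)
        a_f = average_events(rec_f, _events(onsets_few), window=(5.0, 15.0))
        a_m = average_events(rec_m, _events(onsets_many), window=(5.0, 15.0))
        n_pre = int(5.0 / 0.1)
        resid_f = np.std(-a_f.samples[n_pre : n_pre + 100] - 25.0 * kernel[:100])
        resid_m = np.std(-a_m.samples[n_pre : n_pre + 100] - 25.0 * kernel[:100])
        assert resid_m < resid_f / 1.8  # ~ sqrt(9) ideal shrinkage

    def test_overlapping_events_excluded(self):
        onsets = [500.0, 1500.0, 1507.0, 2500.0, 3500.0]
        rec, _ = self._make_recording(onsets)
        avg = average_events(rec, _events(onsets), window=(5.0, 15.0))
        assert avg.annotations["n_used"] == 3
        assert avg.annotations["n_excluded"] == 2

    def test_too_few_events_rejected(self):
        rec, _ = self._make_recording([500.0, 1500.0])
        with pytest.raises(ValueError):
            average_events(rec, _events([500.0, 1500.0]), window=(5.0, 15.0))


class TestChargeTransfer:
    def test_rectangle(self):
        sw = Sweep(0.1, np.r_[np.zeros(100), -100 * np.ones(101), np.zeros(100)])
        q = charge_transfer(sw, (10.0, 20.0))
        assert q == pytest.approx(1000.0, rel=1e-6)

    def test_exponential_integral(self):
        t = np.arange(0, 125.0, 0.01)
        sw = Sweep(0.01, -100 * np.exp(-t / 12.5))
        q = charge_transfer(sw, (0.0, 124.99))
        assert q == pytest.approx(100 * 12.5, rel=1e-3)

    def test_zero_trace(self):
        sw = Sweep(0.1, np.zeros(1000))
        assert charge_transfer(sw, (0.0, 50.0)) == 0.0

    def test_additive_over_disjoint_windows(self):
        rng = np.random.default_rng(9)
        sw = Sweep(0.1, -np.abs(rng.normal(5, 1, 2000)))
        q = charge_transfer(sw, (0.0, 100.0))
        q1 = charge_transfer(sw, (0.0, 50.0))
        q2 = charge_transfer(sw, (50.0, 100.0))
        assert q == pytest.approx(q1 + q2, rel=1e-9)

    def test_window_outside_rejected(self):
        sw = Sweep(0.1, np.zeros(100))
        with pytest.raises(ValueError):
            charge_transfer(sw, (0.0, 50.0))


class TestPairedPulseRatio:
    def test_non_overlapping_identical_pulses(self):
        ens = generate_eepsc_pair(amp1=100.0, true_ppr=1.0, interval=300.0,
                                  decay_tau=5.0, noise_sd=0.0, seed=0)
        sw = average_sweeps(ens)
        assert paired_pulse_ratio(sw, 20.0, 320.0) == pytest.approx(1.0, rel=1e-6)

    def test_correction_recovers_true_ppr(self):
        ens = generate_eepsc_pair(amp1=100.0, true_ppr=1.5, interval=50.0,
                                  decay_tau=12.5, noise_sd=0.0, seed=0)
        sw = average_sweeps(ens)
        raw = paired_pulse_ratio(sw, 20.0, 70.0, correction="none")
        cor = paired_pulse_ratio(sw, 20.0, 70.0, correction="decay_subtraction")
        assert raw == pytest.approx(1.5 + np.exp(-4.0), abs=1e-3)
        assert cor == pytest.approx(1.5, rel=0.01)

    def test_zero_first_peak_rejected(self):
        sw = Sweep(0.1, np.zeros(2000), {"onset": 20.0})
        with pytest.raises(ValueError):
            paired_pulse_ratio(sw, 20.0, 70.0)


class TestNmdarAmplitude:
    def test_dual_component_analytic(self):
        # fast tau 10 ms fully decayed by 150 ms; slow 20 pA tau 100 ms remains
        t = np.arange(0, 250, 0.1)
        y = 60 * np.exp(-t / 10.0) + 20 * np.exp(-t / 100.0)
        sw = Sweep(0.1, y, {"vh": 40.0})
        val = nmdar_amplitude(sw, stim_time=0.0)
        assert val == pytest.approx(20 * np.exp(-1.5), rel=0.01)

    def test_zero_trace(self):
        sw = Sweep(0.1, np.zeros(2500), {"vh": 40.0})
        assert nmdar_amplitude(sw, stim_time=0.0) == 0.0

    def test_short_sweep_rejected(self):
        sw = Sweep(0.1, np.zeros(1000), {"vh": 40.0})
        with pytest.raises(ValueError):
            nmdar_amplitude(sw, stim_time=0.0)

    def test_wrong_holding_rejected(self):
        sw = Sweep(0.1, np.zeros(2500), {"vh": -70.0})
        with pytest.raises(ValueError):
            nmdar_amplitude(sw, stim_time=0.0)
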