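"""Deterministic master-equation oracle and stochastic ensemble simulator."""

import numpy as np
import pytest

from ampar_kinetics import (
    ChannelParams,
    KineticScheme,
    NoiseModel,
    Transition,
    build_scheme,
    make_stimulus,
    mean_occupancy,
    simulate_ensemble,
)


@pytest.fixture
def two_state():
    return KineticScheme(
        states=("R", "O"),
        conducting=(False, True),
        resting="R",
        transitions=(Transition("R", "O", 0.5, True), Transition("O", "R", 1.0)),
    )


class TestMeanOccupancy:
    def test_two_state_closed_form(self, two_state):
        c = 4.0
        stim = make_stimulus("custom", dt=0.01, exchange_tau=0.0,
                             concentration=np.full(3000, c))
        traj = mean_occupancy(two_state, stim)
        kp, km = 0.5 * c, 1.0
        tau, pinf = 1 / (kp + km), kp / (kp + km)
        closed = pinf * (1 - np.exp(-traj.time / tau))
        assert np.abs(traj.open_fraction - closed).max() < 1e-4

    def test_zero_concentration_stays_resting(self):
        sch = build_scheme("wt")
        stim = make_stimulus("custom", dt=0.01, concentration=np.zeros(500))
        traj = mean_occupancy(sch, stim)
        np.testing.assert_allclose(traj.state("R"), 1.0, atol=1e-12)

    @pytest.mark.parametrize("preset", ["wt", "gof"])
    @pytest.mark.parametrize("protocol", ["deactivation", "desensitization"])
    def test_conservation(self, preset, protocol):
        stim = make_stimulus(protocol, dt=0.01)
        traj = mean_occupancy(build_scheme(preset), stim)
        assert np.abs(traj.occupancy.sum(axis=1) - 1.0).max() < 1e-9
        assert traj.occupancy.min() >= 0.0

    def test_stiffness_violation_raises(self, two_state):
        stim = make_stimulus("custom", dt=1.0, concentration=np.full(10, 10.0))
        fast = KineticScheme(
            states=("R", "O"), conducting=(False, True), resting="R",
            transitions=(Transition("R", "O", 5.0, True), Transition("O", "R", 1.0)),
        )
        with pytest.raises(ValueError, match="dt too coarse"):
            mean_occupancy(fast, stim)


class TestSimulateEnsemble:
    def test_zero_channels_pure_noise(self):
        sch = build_scheme("wt")
        stim = make_stimulus("deactivation", dt=0.01)
        ens = simulate_ensemble(
            sch, stim, ChannelParams(0, 16.8), NoiseModel(baseline_sd=2.0), 20, seed=3
        )
        assert abs(ens.data.mean()) < 3 * 2.0 / np.sqrt(ens.data.size)

    def test_seed_determinism(self):
        sch = build_scheme("wt")
        stim = make_stimulus("deactivation", dt=0.01)
        ch, noise = ChannelParams(16, 16.8), NoiseModel(baseline_sd=1.0)
        a = simulate_ensemble(sch, stim, ch, noise, 5, seed=42)
        b = simulate_ensemble(sch, stim, ch, noise, 5, seed=42)
        c = simulate_ensemble(sch, stim, ch, noise, 5, seed=43)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_inward_current_negative_at_minus70(self):
        sch = build_scheme("gof")
        stim = make_stimulus("deactivation", dt=0.01)
        ch = ChannelParams(64, 16.8, vh=-70.0, vr=0.0)
        assert ch.unitary_current == pytest.approx(-1.176)
        ens = simulate_ensemble(sch, stim, ch, NoiseModel(), 10, seed=1)
        assert ens.data.min() < -10.0  # inward peak
        assert ens.data.max() <= 0.0  # no outward excursions without noise

    def test_pooled_mean_matches_oracle(self):
        # modest-size agreement check; the full-scale bound is in acceptance
        sch = build_scheme("gof")
        stim = make_stimulus("deactivation", dt=0.01, tail=19.0)
        ch = ChannelParams(500, 16.8)
        ens = simulate_ensemble(sch, stim, ch, NoiseModel(), 40, seed=5)
        pooled = ens.data.mean(axis=0) / ch.unitary_current / ch.n_channels
        p = mean_occupancy(sch, stim).open_fraction
        assert np.abs(pooled - p).max() / p.max() < 0.05

    def test_missing_seed_rejected(self):
        sch = build_scheme("wt")
        stim = make_stimulus("deactivation", dt=0.01)
        with pytest.raises(ValueError):
            simulate_ensemble(sch, stim, ChannelParams(4, 16.8), NoiseModel(), 5, seed=None)

    def test_metadata_carries_provenance(self):
        sch = build_scheme("wt")
        stim = make_stimulus("deactivation", dt=0.01)
        ens = simulate_ensemble(sch, stim, ChannelParams(4, 16.8), NoiseModel(), 2, seed=9)
        assert ens.metadata["seed"] == 9
        assert ens.metadata["scheme"] == "wt"
        assert ens.metadata["vh"] == -70.0
        assert ens.metadata["onset"] == stim.onset

    def test_rundown_scales_sweeps(self):
        sch = build_scheme("gof")
        stim = make_stimulus("deactivation", dt=0.01)
        ch = ChannelParams(2000, 16.8)
        factors = np.linspace(1.0, 0.5, 6)
        ens = simulate_ensemble(
            sch, stim, ch, NoiseModel(rundown_factors=factors), 6, seed=2
        )
        peaks = np.abs(ens.data).max(axis=1)
        assert peaks[-1] < 0.65 * peaks[0]
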