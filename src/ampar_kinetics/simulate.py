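"""Deterministic and stochastic simulation of channel ensembles.

Two engines share one discretisation: the agonist concentration is held
piecewise-constant over each sample interval, and per interval the channel
obeys the continuous-time Markov chain of the gating scheme.

``mean_occupancy`` propagates the master equation dp/dt = p @ Q(c(t)) with
the exact interval propagator expm(Q dt) (cached per unique concentration),
starting from the resting state.  ``simulate_ensemble`` draws per-channel
state paths from the *same* one-step transition matrices, so the ensemble
mean converges to the deterministic oracle with pure Monte-Carlo error and
no discretisation bias.  Trace current is

    I(t) = (open channels) * gamma * (Vh - Vr) * 1e-3   [pA]

(gamma in pS, potentials in mV), i.e. inward currents are negative at a
holding potential of -70 mV, plus Gaussian baseline noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import expm

from .schemes import KineticScheme
from .stimuli import StimulusWaveform
from .traces import TraceEnsemble

__all__ = [
    "ChannelParams",
    "NoiseModel",
    "StateTrajectory",
    "mean_occupancy",
    "simulate_ensemble",
    "linear_rundown",
]

MAX_RATE_DT = 0.1  # stiffness guard: max total exit rate * dt must stay below this


@dataclass
class ChannelParams:
    """Patch-level channel population parameters."""

    n_channels: int
    gamma: float  # unitary conductance, pS
    vh: float = -70.0  # holding potential, mV
    vr: float = 0.0  # reversal potential, mV

    def __post_init__(self):
        if self.n_channels < 0:
            raise ValueError("n_channels must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.vh == self.vr:
            raise ValueError("holding and reversal potential must differ")

    @property
    def unitary_current(self) -> float:
        """Signed single-channel current in pA (negative = inward)."""
        return self.gamma * (self.vh - self.vr) * 1e-3


@dataclass
class NoiseModel:
    """Additive Gaussian baseline noise and optional per-sweep rundown."""

    baseline_sd: float = 0.0  # pA
    rundown_factors: np.ndarray | None = None  # multiplicative, one per sweep

    def __post_init__(self):
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if self.rundown_factors is not None:
            self.rundown_factors = np.asarray(self.rundown_factors, dtype=float)
            if np.any(self.rundown_factors <= 0):
                raise ValueError("rundown factors must be > 0")

    def factors(self, n_sweeps: int) -> np.ndarray:
        if self.rundown_factors is None:
            return np.ones(n_sweeps)
        if self.rundown_factors.size != n_sweeps:
            raise ValueError("rundown schedule length must equal n_sweeps")
        return self.rundown_factors


def linear_rundown(n_sweeps: int, final_scale: float = 0.7) -> np.ndarray:
    """Linearly declining per-sweep scale from 1 to ``final_scale``."""
    return np.linspace(1.0, final_scale, n_sweeps)


@dataclass
class StateTrajectory:
    """Deterministic state occupancies on the stimulus time grid."""

    dt: float
    occupancy: np.ndarray  # (n_samples, n_states)
    states: tuple[str, ...]
    conducting: tuple[bool, ...]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[0]) * self.dt

    @property
    def open_fraction(self) -> np.ndarray:
        mask = np.asarray(self.conducting)
        return self.occupancy[:, mask].sum(axis=1)

    def state(self, label: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(label)]


def _check_stiffness(scheme: KineticScheme, stim: StimulusWaveform) -> None:
    worst = scheme.max_exit_rate(float(stim.concentration.max()))
    if worst * stim.dt >= MAX_RATE_DT:
        raise ValueError(
            f"dt too coarse for this scheme: max exit rate {worst:.3g}/ms * "
            f"dt {stim.dt} ms = {worst * stim.dt:.3g} >= {MAX_RATE_DT}"
        )


def _step_propagators(
    scheme: KineticScheme, stim: StimulusWaveform
) -> tuple[np.ndarray, np.ndarray]:
    """Exact one-step transition matrices, cached per unique concentration.

    Returns (mats, index) with mats of shape (n_unique, S, S) and index[t]
    selecting the matrix that propagates sample t -> t+1.
    """
    conc = stim.concentration
    uniq, index = np.unique(conc, return_inverse=True)
    mats = np.empty((uniq.size, scheme.n_states, scheme.n_states))
    for u, c in enumerate(uniq):
        mats[u] = expm(scheme.generator(float(c)) * stim.dt)
    np.clip(mats, 0.0, None, out=mats)
    mats /= mats.sum(axis=2, keepdims=True)
    return mats, index.astype(np.int64)


def mean_occupancy(scheme: KineticScheme, stim: StimulusWaveform) -> StateTrajectory:
    """Solve the master equation along the stimulus; the resting state is
    fully occupied at t = 0 and occupancies sum to one at every sample.

    Propagation is exact per sample interval (matrix exponential of the
    generator at the interval's concentration); long constant-concentration
    stretches are advanced in one vectorised eigendecomposition step.
    """
    _check_stiffness(scheme, stim)
    mats, index = _step_propagators(scheme, stim)
    n = stim.concentration.size
    occ = np.empty((n, scheme.n_states))
    p = np.zeros(scheme.n_states)
    p[scheme.resting_index] = 1.0
    occ[0] = p
    # sample t is reached via the propagator at concentration sample t-1
    index = index[: n - 1]
    # run-length encode the per-step propagator index
    change = np.flatnonzero(np.diff(index)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, index.size]
    pos = 1  # next sample to fill
    for s, e in zip(starts, ends):
        m = mats[index[s]]
        length = e - s  # steps sharing this propagator fill samples s+1 .. e
        if length < 8:
            for _ in range(length):
                p = p @ m
                occ[pos] = p
                pos += 1
            continue
        w, v = np.linalg.eig(m)
        cond = np.linalg.cond(v)
        if not np.isfinite(cond) or cond > 1e10:
            for _ in range(length):
                p = p @ m
                occ[pos] = p
                pos += 1
            continue
        vinv = np.linalg.inv(v)
        coeff = p @ v
        ks = np.arange(1, length + 1)
        block = np.real((coeff * w[None, :] ** ks[:, None]) @ vinv)
        np.clip(block, 0.0, None, out=block)
        block /= block.sum(axis=1, keepdims=True)
        occ[pos : pos + length] = block
        p = occ[pos + length - 1]
        pos += length
    return StateTrajectory(stim.dt, occ, scheme.states, scheme.conducting)


@njit(cache=True)
def _simulate_paths(cum, index, open_flags, n_channels, n_sweeps, start_state, seed):
    """Per-channel discrete Markov paths; returns open counts (sweep, time)."""
    np.random.seed(seed)
    n_steps = index.size
    counts = np.zeros((n_sweeps, n_steps), dtype=np.int64)
    n_states = cum.shape[1]
    for s in range(n_sweeps):
        for ch in range(n_channels):
            state = start_state
            if open_flags[state]:
                counts[s, 0] += 1
            for t in range(1, n_steps):
                u = np.random.random()
                row = cum[index[t - 1], state]
                nxt = n_states - 1
                for j in range(n_states):
                    if u < row[j]:
                        nxt = j
                        break
                state = nxt
                if open_flags[state]:
                    counts[s, t] += 1
    return counts


def simulate_ensemble(
    scheme: KineticScheme,
    stim: StimulusWaveform,
    channels: ChannelParams,
    noise: NoiseModel,
    n_sweeps: int,
    seed: int,
) -> TraceEnsemble:
    """Simulate an ensemble of independent N-channel sweeps.

    Each sweep is an independent realisation of ``channels.n_channels``
    channels; identical (params, seed) give bit-identical output.  Scheme,
    channel, noise and seed metadata ride along on the ensemble.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    _check_stiffness(scheme, stim)
    mats, index = _step_propagators(scheme, stim)
    cum = np.cumsum(mats, axis=2)
    open_flags = np.asarray(scheme.conducting)
    counts = _simulate_paths(
        cum,
        index,
        open_flags,
        int(channels.n_channels),
        int(n_sweeps),
        scheme.resting_index,
        int(seed) % 2**32,
    )
    factors = noise.factors(n_sweeps)
    data = counts * channels.unitary_current * factors[:, None]
    if noise.baseline_sd > 0:
        rng = np.random.default_rng(int(seed))
        data = data + rng.normal(0.0, noise.baseline_sd, size=data.shape)
    meta = {
        "protocol": stim.protocol,
        "onset": stim.onset,
        "offset": stim.offset,
        "exchange_tau": stim.exchange_tau,
        "vh": channels.vh,
        "vr": channels.vr,
        "gamma": channels.gamma,
        "n_channels": channels.n_channels,
        "baseline_sd": noise.baseline_sd,
        "seed": int(seed),
        "scheme": scheme.name,
        "rates": scheme.rate_dict(),
    }
    return TraceEnsemble(stim.dt, data, meta)
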