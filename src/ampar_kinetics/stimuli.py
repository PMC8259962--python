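"""Agonist application waveforms for fast-perfusion protocols.

A stimulus is a sampled glutamate concentration profile (mM) on the trace
time grid.  The canonical protocols mirror fast piezo-driven application to
outside-out patches: a 1 ms pulse of 10 mM glutamate probes deactivation, a
500 ms pulse probes desensitization, and a 200 ms pulse is used for the
voltage-step (I-V) family.  Square pulse edges are smoothed with a
first-order filter of time constant ``exchange_tau`` emulating finite
solution exchange (10-90% exchange time = exchange_tau * ln 9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusWaveform", "make_stimulus", "PROTOCOLS"]

GLUTAMATE_MM = 10.0
DEFAULT_EXCHANGE_TAU = 0.1  # ms; 10-90% ~ 0.22 ms, typical of theta-glass piezo steps
BASELINE_MS = 20.0

# pulse duration and post-pulse tail per protocol, ms
PROTOCOLS: dict[str, tuple[float, float]] = {
    "deactivation": (1.0, 29.0),
    "desensitization": (500.0, 80.0),
    "iv_step": (200.0, 80.0),
}


@dataclass
class StimulusWaveform:
    """Concentration samples (mM) on a uniform grid of step ``dt`` ms."""

    dt: float
    concentration: np.ndarray
    onset: float = BASELINE_MS  # ms; nominal pulse onset
    offset: float | None = None  # ms; nominal pulse end (None for custom)
    exchange_tau: float = 0.0
    protocol: str = "custom"

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.concentration.size < 2:
            raise ValueError("stimulus needs at least 2 samples")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.concentration.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.concentration.size - 1) * self.dt


def _smooth_exchange(conc: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """First-order (single-pole) low-pass; exact exponential update per step."""
    if tau == 0:
        return conc
    alpha = 1.0 - np.exp(-dt / tau)
    out = np.empty_like(conc)
    acc = conc[0]
    for i, c in enumerate(conc):
        acc += (c - acc) * alpha
        out[i] = acc
    return out


def make_stimulus(
    protocol: str,
    dt: float = 0.01,
    exchange_tau: float = DEFAULT_EXCHANGE_TAU,
    concentration: float | np.ndarray = GLUTAMATE_MM,
    baseline: float = BASELINE_MS,
    tail: float | None = None,
) -> StimulusWaveform:
    """Build a named application protocol (or wrap a custom profile).

    Parameters
    ----------
    protocol : {"deactivation", "desensitization", "iv_step", "custom"}
        ``deactivation`` = 1 ms pulse, ``desensitization`` = 500 ms,
        ``iv_step`` = 200 ms; ``custom`` takes ``concentration`` as a full
        sample array.
    dt : float
        Sample interval, ms (0.01 ms = 100 kHz by default).
    exchange_tau : float
        Solution-exchange smoothing time constant, ms; 0 gives square edges.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if exchange_tau < 0:
        raise ValueError("exchange_tau must be >= 0")
    if protocol == "custom":
        conc = np.asarray(concentration, dtype=float)
        if conc.ndim != 1:
            raise ValueError("custom protocol needs a 1-d concentration array")
        return StimulusWaveform(dt, _smooth_exchange(conc, dt, exchange_tau),
                                onset=0.0, offset=None,
                                exchange_tau=exchange_tau, protocol="custom")
    if protocol not in PROTOCOLS:
        raise ValueError(
            f"unknown protocol {protocol!r}; expected one of "
            f"{sorted(PROTOCOLS) + ['custom']}"
        )
    pulse, default_tail = PROTOCOLS[protocol]
    if tail is None:
        tail = default_tail
    if baseline < 20.0:
        raise ValueError("pre-pulse baseline must be at least 20 ms")
    n = int(round((baseline + pulse + tail) / dt)) + 1
    conc = np.zeros(n)
    i0 = int(round(baseline / dt))
    i1 = int(round((baseline + pulse) / dt))
    conc[i0:i1] = float(np.max(np.atleast_1d(concentration)))
    return StimulusWaveform(
        dt,
        _smooth_exchange(conc, dt, exchange_tau),
        onset=baseline,
        offset=baseline + pulse,
        exchange_tau=exchange_tau,
        protocol=protocol,
    )
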