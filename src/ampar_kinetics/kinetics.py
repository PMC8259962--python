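"""Peak, rise-time, steady-state and multi-exponential decay measurements.

Decay fitting is the workhorse behind deactivation and desensitization time
constants and synaptic-current decays: the model is

    y(t) = sum_i a_i exp(-(t - t0)/tau_i) + offset,   1 <= i <= 3

fit on the decay window by separable (variable-projection) least squares —
the time constants are optimised with scipy.optimize.least_squares while the
amplitudes and offset are solved linearly at each step, with multi-start
initialisation (tau log-spaced over 0.2-100 ms) to dodge local minima.  The
summary statistic is the amplitude-weighted time constant

    tau_w = sum_i a_i tau_i / sum_i a_i .

The component count is chosen incrementally: k+1 components replace k only
when the residual sum of squares drops by more than 5%.

All measurements operate on magnitudes after baseline subtraction (inward
currents are negative; the sign is restored only in reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .traces import Sweep

__all__ = ["PeakMeasure", "ExpFit", "measure_peak", "fit_decay", "steady_state_fraction"]

TAU_BOUNDS = (1e-3, 1e4)  # ms
RSS_IMPROVEMENT = 0.05  # accept k+1 components only below 0.95 * RSS(k)
N_RESTARTS = 5
TAU_INIT_RANGE = (0.2, 100.0)  # ms


@dataclass
class PeakMeasure:
    """Signed peak amplitude (pA), its time (ms) and the 10-90% rise time."""

    amplitude: float
    t_peak: float
    rise_10_90: float
    degenerate: bool = False


@dataclass
class ExpFit:
    """Multi-exponential decay fit summary."""

    components: list[tuple[float, float]]  # (amplitude pA, tau ms), tau ascending
    offset: float
    weighted_tau: float
    window: tuple[float, float]
    rss: float
    n_components: int
    flags: list[str] = field(default_factory=list)

    @property
    def taus(self) -> list[float]:
        return [tau for _, tau in self.components]

    @property
    def amplitudes(self) -> list[float]:
        return [a for a, _ in self.components]


def measure_peak(sweep: Sweep, window: tuple[float, float] | None = None) -> PeakMeasure:
    """Largest-magnitude extremum in the search window, with 10-90 rise time.

    The sweep must be baseline-corrected; rise time is measured from the
    baseline (zero) level to the peak by linear interpolation of the 10% and
    90% magnitude crossings.
    """
    if window is None:
        onset = sweep.annotations.get("onset", 0.0)
        window = (onset, sweep.duration)
    t0, t1 = window
    i0, i1 = sweep.index_at(t0), sweep.index_at(t1)
    if i1 <= i0:
        raise ValueError("empty peak search window")
    seg = sweep.samples[i0 : i1 + 1]
    k = int(np.argmax(np.abs(seg)))
    amp = float(seg[k])
    if amp == 0.0:
        return PeakMeasure(0.0, t0, 0.0, degenerate=True)
    mag = np.abs(seg[: k + 1])
    peak_mag = abs(amp)

    def _crossing(level: float) -> float:
        above = np.flatnonzero(mag >= level)
        if above.size == 0:
            return 0.0
        j = above[0]
        if j == 0:
            return 0.0
        frac = (level - mag[j - 1]) / (mag[j] - mag[j - 1])
        return (j - 1 + frac) * sweep.dt
    rise = _crossing(0.9 * peak_mag) - _crossing(0.1 * peak_mag)
    return PeakMeasure(amp, t0 + k * sweep.dt, max(rise, 0.0))


def _design(t: np.ndarray, taus: np.ndarray, fit_offset: bool) -> np.ndarray:
    cols = [np.exp(-t / tau) for tau in taus]
    if fit_offset:
        cols.append(np.ones_like(t))
    return np.column_stack(cols)


def _linear_solve(t, y, taus, fit_offset):
    a = _design(t, taus, fit_offset)
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ coef
    return coef, resid


def _fit_k(t, y, k, fit_offset):
    """Best k-component fit over multi-start variable projection."""
    lo, hi = TAU_INIT_RANGE
    hi = min(hi, max(t[-1], 1.0) * 2)
    anchors = np.geomspace(lo, hi, N_RESTARTS)
    best = None
    log_bounds = (np.log(TAU_BOUNDS[0]), np.log(TAU_BOUNDS[1]))
    for anchor in anchors:
        if k == 1:
            taus0 = np.array([anchor])
        else:
            taus0 = np.geomspace(anchor, min(anchor * 4.0**(k - 1), TAU_BOUNDS[1]), k)

        def resid_fn(theta):
            return _linear_solve(t, y, np.exp(theta), fit_offset)[1]

        sol = least_squares(
            resid_fn,
            np.log(taus0),
            bounds=(log_bounds[0], log_bounds[1]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        rss = float(sol.cost * 2)
        if best is None or rss < best[0]:
            best = (rss, np.exp(sol.x))
    rss, taus = best
    coef, resid = _linear_solve(t, y, taus, fit_offset)
    return taus, coef, float(resid @ resid)


def fit_decay(
    sweep: Sweep,
    start: str | float = "peak",
    end: float | None = None,
    max_components: int = 3,
    search_window: tuple[float, float] | None = None,
    fit_offset: bool = True,
) -> ExpFit:
    """Fit the decay of a baseline-corrected current transient.

    Parameters
    ----------
    start : "peak" or float
        Start of the fit window: at the peak sample (default) or, given a
        fraction in (0, 1), at the first post-peak sample whose magnitude
        falls below that fraction of the peak.
    end : float, optional
        End of the fit window in ms (sweep end by default).
    max_components : int
        Largest number of exponential components tried (<= 3).
    """
    if not 1 <= max_components <= 3:
        raise ValueError("max_components must be between 1 and 3")
    pk = measure_peak(sweep, search_window)
    if pk.degenerate:
        raise ValueError("cannot fit decay of an all-zero trace")
    sign = np.sign(pk.amplitude)
    y_full = sign * sweep.samples  # magnitude-positive transient
    i_peak = sweep.index_at(pk.t_peak)
    i_start = i_peak
    if start != "peak":
        frac = float(start)
        if not 0 < frac < 1:
            raise ValueError("fractional start must be in (0, 1)")
        below = np.flatnonzero(y_full[i_peak:] <= frac * abs(pk.amplitude))
        if below.size == 0:
            raise ValueError("trace never decays below the requested start fraction")
        i_start = i_peak + below[0]
    i_end = sweep.samples.size - 1 if end is None else sweep.index_at(end)
    if i_end - i_start < 10:
        raise ValueError("decay window must contain at least 10 samples")
    t = (np.arange(i_start, i_end + 1) - i_start) * sweep.dt
    y = y_full[i_start : i_end + 1]

    scale2 = max(float(np.max(np.abs(y))) ** 2, 1e-300)
    floor = 1e-20 * scale2 * y.size
    flags: list[str] = []
    fits = {}
    chosen = 1
    for k in range(1, max_components + 1):
        fits[k] = _fit_k(t, y, k, fit_offset)
        if k > 1:
            if fits[k][2] < (1 - RSS_IMPROVEMENT) * fits[chosen][2]:
                chosen = k
        if fits[k][2] < floor:
            break
    taus, coef, rss = fits[chosen]
    amps = coef[: chosen]
    offset = float(coef[chosen]) if fit_offset else 0.0
    order = np.argsort(taus)
    comps = [(float(amps[i]), float(taus[i])) for i in order]
    asum = sum(a for a, _ in comps)
    if asum == 0:
        flags.append("zero-amplitude-sum")
        tau_w = float("nan")
    else:
        tau_w = sum(a * tau for a, tau in comps) / asum
    for _, tau in comps:
        if tau <= TAU_BOUNDS[0] * 1.01 or tau >= TAU_BOUNDS[1] * 0.99:
            flags.append("tau-at-bound")
    return ExpFit(
        components=comps,
        offset=offset,
        weighted_tau=tau_w,
        window=(i_start * sweep.dt, i_end * sweep.dt),
        rss=rss,
        n_components=chosen,
        flags=flags,
    )


def steady_state_fraction(
    sweep: Sweep,
    pulse_offset: float | None = None,
    steady_window: float = 50.0,
) -> float:
    """Steady-state current as a percentage of the peak.

    Mean magnitude over the last ``steady_window`` ms of the agonist pulse
    (ending at ``pulse_offset``) divided by the peak magnitude, * 100.
    """
    onset = sweep.annotations.get("onset", 0.0)
    if pulse_offset is None:
        pulse_offset = sweep.annotations.get("offset")
        if pulse_offset is None:
            raise ValueError("pulse offset time required (argument or annotation)")
    if pulse_offset - steady_window < onset:
        raise ValueError("steady window extends before the pulse onset")
    if pulse_offset > sweep.duration + 1e-9:
        raise ValueError("pulse offset beyond the trace")
    pk = measure_peak(sweep, (onset, pulse_offset))
    if pk.degenerate:
        raise ValueError("zero peak; steady-state fraction undefined")
    i0 = sweep.index_at(pulse_offset - steady_window)
    i1 = sweep.index_at(pulse_offset)
    sign = np.sign(pk.amplitude)
    steady = float(np.mean(sign * sweep.samples[i0 : i1 + 1]))
    return 100.0 * steady / abs(pk.amplitude)
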