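"""Current-voltage (I-V) curves and rectification.

Peak currents are taken per holding potential within the agonist application
window, normalized to the absolute peak current at the -100 mV reference
(so the normalized value at -100 mV is -1 for inward reference currents).
The rectification index is the symmetric-voltage ratio

    RI = |I(+60)| / |I(-60)|

with +/-60 mV values linearly interpolated from neighbours when the family
was not sampled there; RI = 1 for any odd-symmetric (linear) I-V relation
and < 1 for inwardly rectifying ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import measure_peak
from .traces import TraceEnsemble, average_sweeps

__all__ = ["IVCurve", "build_iv", "rectification_index"]

REFERENCE_MV = -100.0
RI_VOLTAGE = 60.0


@dataclass
class IVCurve:
    voltages: np.ndarray  # mV, strictly increasing
    currents: np.ndarray  # signed peak currents, pA
    normalized: np.ndarray  # currents / |I(reference)|
    reference_mv: float = REFERENCE_MV

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


def build_iv(
    ensembles: dict[float, TraceEnsemble],
    window: tuple[float, float] | None = None,
) -> IVCurve:
    """Peak current per holding voltage, normalized by |I(-100 mV)|.

    ``ensembles`` maps holding potential (mV) to a baseline-corrected
    ensemble; peaks are measured on the average sweep within the agonist
    application window (onset to offset annotation unless given).
    """
    if REFERENCE_MV not in ensembles:
        raise ValueError(f"I-V family must include the {REFERENCE_MV:g} mV reference")
    voltages = np.array(sorted(ensembles))
    currents = []
    for v in voltages:
        avg = average_sweeps(ensembles[v])
        win = window
        if win is None:
            onset = avg.annotations.get("onset", 0.0)
            offset = avg.annotations.get("offset", avg.duration)
            win = (onset, offset)
        currents.append(measure_peak(avg, win).amplitude)
    currents = np.array(currents)
    ref = abs(currents[voltages.tolist().index(REFERENCE_MV)])
    if ref == 0:
        raise ValueError("zero peak current at the reference voltage")
    return IVCurve(voltages, currents, currents / ref)


def _interp_current(curve: IVCurve, v: float) -> float:
    if v < curve.voltages[0] or v > curve.voltages[-1]:
        raise ValueError(f"{v} mV outside the sampled voltage range")
    return float(np.interp(v, curve.voltages, curve.currents))


def rectification_index(curve: IVCurve, voltage: float = RI_VOLTAGE) -> float:
    """|I(+60)| / |I(-60)| (values interpolated if those voltages are absent)."""
    i_neg = _interp_current(curve, -voltage)
    i_pos = _interp_current(curve, +voltage)
    if i_neg == 0:
        raise ValueError(f"zero current at -{voltage:g} mV; RI undefined")
    return abs(i_pos) / abs(i_neg)
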