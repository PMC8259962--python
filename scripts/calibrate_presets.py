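"""Calibrate the wt/gof preset rate constants of the shipped 4-state scheme.

The phenotypic targets (deactivation tau, weighted desensitization tau,
steady-state percentage, peak open probability) are fit with the
deterministic master-equation oracle; the resulting rates are frozen as
named constants in ampar_kinetics.schemes.  Run from the repo root:

    python scripts/calibrate_presets.py
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from ampar_kinetics.schemes import KineticScheme, Transition
from ampar_kinetics.simulate import mean_occupancy
from ampar_kinetics.stimuli import make_stimulus
from ampar_kinetics.traces import Sweep
from ampar_kinetics.kinetics import fit_decay, steady_state_fraction

RATE_NAMES = ["k_on", "k_off", "k_op", "k_cl", "k_des", "k_res"]

# (tau_deact ms, weighted tau_des ms, steady-state %, peak open probability)
TARGETS = {
    "wt": (0.7, 4.7, 0.7, 0.50),
    "gof": (1.8, 12.9, 28.1, 0.56),
}

X0 = {
    "wt": dict(k_on=0.9, k_off=5.5, k_op=3.7, k_cl=2.4, k_des=0.5, k_res=0.0015),
    "gof": dict(k_on=0.5, k_off=1.5, k_op=4.0, k_cl=1.2, k_des=0.12, k_res=0.035),
}

BOUNDS_LO = dict(k_on=0.05, k_off=0.2, k_op=0.5, k_cl=0.2, k_des=0.005, k_res=1e-4)
BOUNDS_HI = dict(k_on=0.95, k_off=7.0, k_op=7.0, k_cl=7.0, k_des=2.0, k_res=0.5)


def scheme_from(rates: dict[str, float]) -> KineticScheme:
    return KineticScheme(
        states=("R", "B", "O", "D"),
        conducting=(False, False, True, False),
        resting="R",
        transitions=(
            Transition("R", "B", rates["k_on"], True),
            Transition("B", "R", rates["k_off"]),
            Transition("B", "O", rates["k_op"]),
            Transition("O", "B", rates["k_cl"]),
            Transition("O", "D", rates["k_des"]),
            Transition("D", "O", rates["k_res"]),
        ),
    )


def phenotype(rates: dict[str, float]) -> tuple[float, float, float, float]:
    sch = scheme_from(rates)
    des = make_stimulus("desensitization", dt=0.01)
    deact = make_stimulus("deactivation", dt=0.01)
    tr_des = mean_occupancy(sch, des).open_fraction
    tr_de = mean_occupancy(sch, deact).open_fraction
    # decimate the long trace for fit speed; noiseless, so no information lost
    sw_des = Sweep(0.1, -tr_des[::10], {"onset": des.onset, "offset": des.offset})
    sw_de = Sweep(0.01, -tr_de, {"onset": deact.onset})
    f_des = fit_decay(sw_des, end=des.offset, max_components=3,
                      search_window=(des.onset, des.onset + 20.0))
    f_de = fit_decay(sw_de, max_components=2,
                     search_window=(deact.onset, deact.onset + 10.0))
    ss = steady_state_fraction(sw_des, des.offset)
    popen = float(tr_des.max())
    return f_de.weighted_tau, f_des.weighted_tau, ss, popen


def calibrate(preset: str) -> dict[str, float]:
    tgt = np.array(TARGETS[preset])
    lo = np.log([BOUNDS_LO[n] for n in RATE_NAMES])
    hi = np.log([BOUNDS_HI[n] for n in RATE_NAMES])

    def resid(theta):
        rates = dict(zip(RATE_NAMES, np.exp(theta)))
        # keep per-state exit rates below 10/ms at 10 mM (integrator guard)
        pen = []
        for tot in (10 * rates["k_on"], rates["k_off"] + rates["k_op"],
                    rates["k_cl"] + rates["k_des"], rates["k_res"]):
            pen.append(max(0.0, tot - 9.5) * 10.0)
        try:
            ph = np.array(phenotype(rates))
        except Exception:
            return np.array([10.0] * 4 + pen)
        return np.concatenate([np.log(ph / tgt), pen])

    x0 = np.log([X0[preset][n] for n in RATE_NAMES])
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10,
                        diff_step=1e-4)
    rates = dict(zip(RATE_NAMES, np.exp(sol.x)))
    return rates


if __name__ == "__main__":
    for preset in ("wt", "gof"):
        rates = calibrate(preset)
        ph = phenotype(rates)
        print(f"{preset}: " + ", ".join(f"{n}={v:.5f}" for n, v in rates.items()))
        print(f"  tau_deact={ph[0]:.3f} ms  tau_w_des={ph[1]:.3f} ms  "
              f"steady={ph[2]:.3f} %  peak_popen={ph[3]:.3f}")
        print("  target   ", TARGETS[preset])
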