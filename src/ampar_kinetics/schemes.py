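"""Markov gating schemes for ligand-gated channels.

The shipped topology is the minimal four-state chain

    R  <=>  B  <=>  O  <=>  D
   rest   bound   open   desensitized

with the resting->bound step proportional to agonist concentration
(effective rate = k_on * c, c in mM).  This is the smallest scheme that
expresses distinct deactivation (agonist unbinding after a brief pulse),
desensitization (entry into D during sustained agonist) and a tunable
non-zero steady-state open fraction, which is exactly the phenotype space
the analyses downstream need to see.

Two presets ship: ``wt`` reproduces a fast, fully desensitizing wild-type
AMPA-receptor phenotype and ``gof`` a gain-of-function phenotype with slowed
deactivation/desensitization and a sustained (~28% of peak) steady-state
current.  Rate constants were calibrated against the deterministic
master-equation oracle by ``scripts/calibrate_presets.py`` and are frozen
here as named constants; the calibration targets are phenotypic (time
constants and steady-state fraction), not microscopic rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Transition", "KineticScheme", "build_scheme", "WT_RATES", "GOF_RATES"]


@dataclass(frozen=True)
class Transition:
    """Directed transition with a rate constant in ms^-1 (mM^-1 ms^-1 when
    ligand-dependent; the effective rate is rate * concentration)."""

    source: str
    target: str
    rate: float
    ligand_dependent: bool = False

    def effective_rate(self, concentration_mm: float) -> float:
        return self.rate * concentration_mm if self.ligand_dependent else self.rate


@dataclass
class KineticScheme:
    """States plus directed transitions of a channel gating model."""

    states: tuple[str, ...]
    conducting: tuple[bool, ...]
    resting: str
    transitions: tuple[Transition, ...]
    name: str = "custom"

    def __post_init__(self):
        if len(self.states) != len(set(self.states)):
            raise ValueError("duplicate state labels")
        if len(self.conducting) != len(self.states):
            raise ValueError("conducting flags must match states")
        if not any(self.conducting):
            raise ValueError("at least one state must conduct")
        if self.resting not in self.states:
            raise ValueError(f"resting state {self.resting!r} not among states")
        idx = {s: i for i, s in enumerate(self.states)}
        for tr in self.transitions:
            if tr.source not in idx or tr.target not in idx:
                raise ValueError(f"transition {tr} references unknown state")
            if tr.rate < 0:
                raise ValueError(f"negative rate constant on {tr.source}->{tr.target}")
        # connectivity of the undirected transition graph
        adj = {s: set() for s in self.states}
        for tr in self.transitions:
            adj[tr.source].add(tr.target)
            adj[tr.target].add(tr.source)
        seen, stack = set(), [self.resting]
        while stack:
            s = stack.pop()
            if s in seen:
                continue
            seen.add(s)
            stack.extend(adj[s] - seen)
        if seen != set(self.states):
            raise ValueError("transition graph is not connected")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def resting_index(self) -> int:
        return self.states.index(self.resting)

    @property
    def conducting_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.conducting))

    def generator(self, concentration_mm: float) -> np.ndarray:
        """Generator matrix Q at one agonist concentration.

        Row convention for dp/dt = p @ Q: Q[i, j] (i != j) is the i->j rate,
        diagonal entries close each row to zero.
        """
        n = self.n_states
        idx = {s: i for i, s in enumerate(self.states)}
        q = np.zeros((n, n))
        for tr in self.transitions:
            q[idx[tr.source], idx[tr.target]] += tr.effective_rate(concentration_mm)
        np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
        return q

    def max_exit_rate(self, concentration_mm: float) -> float:
        q = self.generator(concentration_mm)
        return float((-np.diag(q)).max())

    def rate_dict(self) -> dict[str, float]:
        return {_edge_name(tr): tr.rate for tr in self.transitions}


_EDGE_NAMES = {
    ("R", "B"): "k_on",
    ("B", "R"): "k_off",
    ("B", "O"): "k_op",
    ("O", "B"): "k_cl",
    ("O", "D"): "k_des",
    ("D", "O"): "k_res",
}
_NAME_TO_EDGE = {v: k for k, v in _EDGE_NAMES.items()}


def _edge_name(tr: Transition) -> str:
    return _EDGE_NAMES.get((tr.source, tr.target), f"{tr.source}->{tr.target}")


# Calibrated against the deterministic oracle (scripts/calibrate_presets.py):
# wt targets   tau_deact 0.7 ms, weighted tau_des 4.7 ms, steady state 0.7 %
# gof targets  tau_deact 1.8 ms, weighted tau_des 12.9 ms, steady state 28.1 %
# k_on in mM^-1 ms^-1, all others ms^-1.  Every per-state total exit rate stays
# below 10 ms^-1 at 10 mM so the dt = 0.01 ms integrator precondition holds.
WT_RATES: dict[str, float] = {
    "k_on": 0.90027,
    "k_off": 5.76817,
    "k_op": 3.73190,
    "k_cl": 2.36342,
    "k_des": 0.49865,
    "k_res": 0.00137,
}

GOF_RATES: dict[str, float] = {
    "k_on": 0.52967,
    "k_off": 2.24928,
    "k_op": 3.98279,
    "k_cl": 1.81428,
    "k_des": 0.09764,
    "k_res": 0.02075,
}

_PRESETS = {"wt": WT_RATES, "gof": GOF_RATES}


def build_scheme(preset: str, rate_overrides: dict[str, float] | None = None) -> KineticScheme:
    """Construct the shipped four-state scheme with preset rate constants.

    Parameters
    ----------
    preset : {"wt", "gof"}
        ``wt`` = fast, fully desensitizing phenotype; ``gof`` = slowed,
        partially non-desensitizing gain-of-function phenotype.
    rate_overrides : dict, optional
        Mapping of rate names (``k_on``, ``k_off``, ``k_op``, ``k_cl``,
        ``k_des``, ``k_res``) to replacement values, applied last.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(_PRESETS)}")
    rates = dict(_PRESETS[preset])
    if rate_overrides:
        for name, value in rate_overrides.items():
            if name not in rates:
                raise KeyError(f"override {name!r} does not name a transition rate")
            if value < 0:
                raise ValueError(f"rate {name} must be >= 0, got {value}")
            rates[name] = float(value)
    transitions = tuple(
        Transition(src, dst, rates[name], ligand_dependent=(name == "k_on"))
        for name, (src, dst) in ((n, _NAME_TO_EDGE[n]) for n in rates)
    )
    return KineticScheme(
        states=("R", "B", "O", "D"),
        conducting=(False, False, True, False),
        resting="R",
        transitions=transitions,
        name=preset,
    )
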