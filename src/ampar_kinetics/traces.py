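"""Trace containers and text/JSON round-trip shared by every analysis stage.

Units are fixed package-wide: time in ms, current in pA, voltage in mV,
conductance in pS.  Sweeps carry their own sample interval ``dt`` and an
annotation mapping with protocol metadata; the stimulus onset is explicit
metadata (key ``"onset"``), never inferred from the samples.

The canonical on-disk dialect is a tab-delimited matrix (column 1 = time in
ms, columns 2..n = sweeps in pA) plus a JSON sidecar ``<path>.json`` holding
the annotations, so that ``read_ensemble(write_ensemble(x))`` reproduces
samples to better than 1e-9 pA and metadata bit-exactly.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sweep",
    "TraceEnsemble",
    "Recording",
    "write_ensemble",
    "read_ensemble",
    "write_recording",
    "read_recording",
    "baseline_correct",
    "average_sweeps",
]


@dataclass
class Sweep:
    """A single current trace on a uniform time base.

    Parameters
    ----------
    dt : float
        Sample interval in ms (> 0).
    samples : numpy.ndarray
        Current samples in pA.
    annotations : dict
        Free-form metadata. Recognised keys include ``protocol``, ``vh``
        (holding potential, mV), ``vr`` (reversal potential, mV), ``onset``
        (stimulus onset, ms from sweep start), ``seed``.
    """

    dt: float
    samples: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a sweep needs at least 2 samples")

    @property
    def time(self) -> np.ndarray:
        """Time base in ms, starting at 0."""
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) * self.dt

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` ms."""
        return int(round(t / self.dt))

    def copy(self) -> "Sweep":
        return Sweep(self.dt, self.samples.copy(), dict(self.annotations))


@dataclass
class TraceEnsemble:
    """Repeated sweeps sharing one time base and protocol.

    ``data`` is a (n_sweeps, n_samples) array; all sweeps share ``dt`` and
    the metadata mapping.
    """

    dt: float
    data: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.data.shape[1] < 2:
            raise ValueError("sweeps need at least 2 samples")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def sweep(self, k: int) -> Sweep:
        return Sweep(self.dt, self.data[k].copy(), dict(self.metadata))

    def copy(self) -> "TraceEnsemble":
        return TraceEnsemble(self.dt, self.data.copy(), dict(self.metadata))


@dataclass
class Recording:
    """Gap-free continuous recording (one long sweep)."""

    sweep: Sweep

    def __post_init__(self):
        if self.sweep.duration < 1000.0:
            raise ValueError(
                "gap-free recordings must be at least 1 s long for event analysis"
            )

    @property
    def dt(self) -> float:
        return self.sweep.dt

    @property
    def sampling_rate_khz(self) -> float:
        return 1.0 / self.sweep.dt


def _sidecar(path: str) -> str:
    return str(path) + ".json"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_ensemble(ensemble: TraceEnsemble, path: str) -> None:
    """Write an ensemble as a delimited text matrix plus JSON sidecar."""
    t = ensemble.time
    mat = np.column_stack([t, ensemble.data.T])
    np.savetxt(path, mat, fmt="%.17g", delimiter="\t")
    meta = {"dt": ensemble.dt, "n_sweeps": ensemble.n_sweeps}
    meta.update(_jsonable(ensemble.metadata))
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_ensemble(path: str) -> TraceEnsemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    if not os.path.exists(_sidecar(path)):
        raise FileNotFoundError(f"missing metadata sidecar {_sidecar(path)}")
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    try:
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed or ragged trace matrix in {path}") from exc
    if mat.shape[1] < 2:
        raise ValueError(f"{path} has no sweep columns")
    dt = float(meta.pop("dt"))
    n_sweeps = int(meta.pop("n_sweeps", mat.shape[1] - 1))
    if n_sweeps != mat.shape[1] - 1:
        raise ValueError(
            f"sidecar declares {n_sweeps} sweeps but file has {mat.shape[1] - 1}"
        )
    return TraceEnsemble(dt, mat[:, 1:].T.copy(), meta)


def write_recording(recording: Recording, path: str) -> None:
    ens = TraceEnsemble(
        recording.dt, recording.sweep.samples[None, :], dict(recording.sweep.annotations)
    )
    write_ensemble(ens, path)


def read_recording(path: str) -> Recording:
    ens = read_ensemble(path)
    if ens.n_sweeps != 1:
        raise ValueError(f"{path} holds {ens.n_sweeps} sweeps, expected 1 recording")
    return Recording(Sweep(ens.dt, ens.data[0], ens.metadata))


def baseline_correct(sweep: Sweep, window: tuple[float, float] | None = None) -> Sweep:
    """Subtract the mean of a pre-stimulus window.

    ``window = (t0, t1)`` in ms must precede the annotated stimulus onset and
    span at least 1 ms; when omitted it defaults to everything from 1 ms
    after sweep start up to 1 ms before the onset. The subtracted offset is
    recorded under annotation key ``"baseline_offset"``.
    """
    onset = sweep.annotations.get("onset")
    if window is None:
        if onset is None:
            raise ValueError("no window given and no stimulus onset annotated")
        window = (0.0, max(1.0, onset - 1.0))
    t0, t1 = window
    if t1 - t0 < 1.0:
        raise ValueError("baseline window must span at least 1 ms")
    if t0 < 0 or t1 > sweep.duration:
        raise ValueError("baseline window outside the trace")
    if onset is not None and t1 > onset + 1e-9:
        raise ValueError(
            f"baseline window [{t0}, {t1}] overlaps the stimulus (onset {onset} ms)"
        )
    i0, i1 = sweep.index_at(t0), sweep.index_at(t1)
    offset = float(np.mean(sweep.samples[i0 : max(i1, i0 + 1)]))
    out = sweep.copy()
    out.samples = out.samples - offset
    out.annotations["baseline_offset"] = offset
    return out


def baseline_correct_ensemble(
    ensemble: TraceEnsemble, window: tuple[float, float] | None = None
) -> TraceEnsemble:
    """Per-sweep baseline correction; offsets recorded in metadata."""
    out = ensemble.copy()
    offsets = []
    for k in range(ensemble.n_sweeps):
        sw = Sweep(ensemble.dt, ensemble.data[k], dict(ensemble.metadata))
        cor = baseline_correct(sw, window)
        out.data[k] = cor.samples
        offsets.append(cor.annotations["baseline_offset"])
    out.metadata["baseline_offsets"] = offsets
    return out


def average_sweeps(ensemble: TraceEnsemble) -> Sweep:
    """Pointwise mean trace; the annotation records how many sweeps went in."""
    if ensemble.n_sweeps < 1:
        raise ValueError("empty ensemble")
    mean = ensemble.data.mean(axis=0)
    ann = dict(ensemble.metadata)
    ann["n_averaged"] = ensemble.n_sweeps
    return Sweep(ensemble.dt, mean, ann)
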