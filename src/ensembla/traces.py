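"""Core data model for extracted miniscope calcium traces.

A recording session is a neuron × frame activity matrix sampled at a fixed
frame rate (10 Hz in the experiments this package targets), together with
behavior bout intervals in seconds and, where sessions are paired, a partial
map identifying the same neuron across sessions.  Everything downstream
(ensemble detection, relevance classification, network inference) consumes
these containers.
"""

from __future__ import annotations

import decimal
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraceMatrix",
    "BoutList",
    "BehaviorVector",
    "IdentityMap",
    "DataError",
    "FormatError",
    "StateError",
    "load_traces",
    "write_traces",
    "load_bouts",
    "write_bouts",
    "zscore_traces",
    "make_behavior_vector",
    "dual_recorded_ids",
    "percent_of_total",
    "format_percent",
    "save_container",
    "load_container",
]

ZSCORE_TOL = 1e-6


class DataError(ValueError):
    """Input data violates an invariant (NaN, negative raw value, ...)."""


class FormatError(ValueError):
    """On-disk file could not be parsed into the expected layout."""


class StateError(RuntimeError):
    """Operation applied to a container in the wrong normalization state."""


@dataclass(frozen=True)
class TraceMatrix:
    """Per-session neuron × frame activity.

    ``normalization`` is either ``"raw_nonneg"`` (extracted fluorescence,
    all values ≥ 0) or ``"zscore"`` (each non-constant row mean 0, SD 1,
    population SD).  ``constant_neurons`` records rows that were constant
    before z-scoring; their z-scored rows are all-zero and downstream
    statistics treat them as missing.
    """

    session_id: str
    neuron_ids: tuple[str, ...]
    frame_rate_hz: float
    activity: np.ndarray
    normalization: str = "raw_nonneg"
    constant_neurons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "neuron_ids", tuple(str(i) for i in self.neuron_ids))
        if act.ndim != 2:
            raise DataError(f"activity must be 2-D, got shape {act.shape}")
        if act.shape[0] != len(self.neuron_ids):
            raise DataError(
                f"{len(self.neuron_ids)} neuron ids but {act.shape[0]} activity rows"
            )
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise DataError("neuron_ids must be unique")
        if act.shape[1] < 2:
            raise DataError("need at least 2 frames")
        if not np.isfinite(act).all():
            raise DataError("activity contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise DataError("frame_rate_hz must be positive")
        if self.normalization not in ("raw_nonneg", "zscore"):
            raise DataError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "raw_nonneg" and (act < 0).any():
            i, j = np.argwhere(act < 0)[0]
            raise DataError(
                f"raw_nonneg trace has negative value at neuron "
                f"{self.neuron_ids[i]!r}, frame {j}"
            )
        if self.normalization == "zscore":
            const = frozenset(self.constant_neurons)
            live = [i for i, nid in enumerate(self.neuron_ids) if nid not in const]
            if live:
                rows = act[live]
                if (np.abs(rows.mean(axis=1)) > ZSCORE_TOL).any() or (
                    np.abs(rows.std(axis=1) - 1.0) > ZSCORE_TOL
                ).any():
                    raise DataError("zscore rows must have mean 0 and SD 1")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def row(self, neuron_id: str) -> np.ndarray:
        return self.activity[self.neuron_ids.index(str(neuron_id))]

    def subset(self, neuron_ids: Sequence[str]) -> "TraceMatrix":
        idx = [self.neuron_ids.index(str(i)) for i in neuron_ids]
        return replace(
            self,
            neuron_ids=tuple(self.neuron_ids[i] for i in idx),
            activity=self.activity[idx].copy(),
            constant_neurons=frozenset(
                n for n in self.constant_neurons if n in set(neuron_ids)
            ),
        )


@dataclass(frozen=True)
class BoutList:
    """Behavior bout intervals ``[start_s, end_s)`` within one session."""

    intervals: tuple[tuple[float, float], ...]
    session_duration_s: float

    def __post_init__(self) -> None:
        iv = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", iv)
        if self.session_duration_s <= 0:
            raise DataError("session_duration_s must be positive")
        prev_end = -np.inf
        for start, end in iv:
            if not (0.0 <= start < end <= self.session_duration_s):
                raise DataError(
                    f"bout ({start}, {end}) outside [0, {self.session_duration_s}]"
                )
            if start < prev_end:
                raise DataError("bout intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def total_bout_s(self) -> float:
        return float(sum(e - s for s, e in self.intervals))


@dataclass(frozen=True)
class BehaviorVector:
    """Per-frame binary indicator of behavior (1 = in bout)."""

    values: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise DataError("behavior vector must be binary")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def is_constant(self) -> bool:
        return bool(self.values.min() == self.values.max())


@dataclass(frozen=True)
class IdentityMap:
    """Partial injective map from session-A neuron ids to session-B ids.

    Produced upstream by multi-session spatial registration; consumed here
    as given for dual-recorded-neuron bookkeeping.
    """

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        p = {str(k): str(v) for k, v in dict(self.pairs).items()}
        if len(set(p.values())) != len(p):
            raise DataError("identity map must be injective")
        object.__setattr__(self, "pairs", p)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_against(self, a: TraceMatrix, b: TraceMatrix) -> None:
        ids_a, ids_b = set(a.neuron_ids), set(b.neuron_ids)
        for ka, vb in self.pairs.items():
            if ka not in ids_a or vb not in ids_b:
                raise DataError(f"identity pair ({ka!r}, {vb!r}) not in sessions")


# ---------------------------------------------------------------------------
# normalization and behavior vectors


def zscore_traces(t: TraceMatrix) -> TraceMatrix:
    """Z-score each neuron's trace (population SD, ddof 0).

    Constant rows become all-zero and are flagged in ``constant_neurons``
    rather than producing NaNs.
    """
    if t.normalization == "zscore":
        raise StateError("traces are already z-scored")
    act = t.activity
    mean = act.mean(axis=1, keepdims=True)
    sd = act.std(axis=1, keepdims=True)
    const = sd[:, 0] <= 0
    safe_sd = np.where(const[:, None], 1.0, sd)
    z = (act - mean) / safe_sd
    z[const] = 0.0
    flagged = frozenset(np.asarray(t.neuron_ids)[const].tolist())
    return replace(t, activity=z, normalization="zscore", constant_neurons=flagged)


def make_behavior_vector(
    bouts: BoutList, frame_rate_hz: float, n_frames: int
) -> BehaviorVector:
    """Discretize bout intervals to a per-frame binary vector.

    Frame ``f`` is 1 iff its midpoint time ``(f + 0.5) / rate`` falls inside
    some half-open interval ``[start, end)``.
    """
    if n_frames < 1:
        raise DataError("n_frames must be positive")
    expected = bouts.session_duration_s * frame_rate_hz
    if abs(n_frames - expected) > 1.0 + 1e-9:
        raise DataError(
            f"n_frames={n_frames} inconsistent with session duration "
            f"{bouts.session_duration_s}s at {frame_rate_hz}Hz (~{expected:.1f})"
        )
    mid = (np.arange(n_frames) + 0.5) / frame_rate_hz
    v = np.zeros(n_frames, dtype=np.int8)
    for start, end in bouts.intervals:
        v[(mid >= start) & (mid < end)] = 1
    return BehaviorVector(values=v, frame_rate_hz=frame_rate_hz)


# ---------------------------------------------------------------------------
# cross-session bookkeeping and display arithmetic


def dual_recorded_ids(
    map_ab: IdentityMap, responsive_a: Iterable[str], responsive_b: Iterable[str]
) -> set[tuple[str, str]]:
    """Pairs (a, b) responsive in both sessions under the identity map."""
    ra, rb = set(map(str, responsive_a)), set(map(str, responsive_b))
    return {(a, b) for a, b in map_ab.pairs.items() if a in ra and b in rb}


def percent_of_total(count: int, total: int) -> float:
    """100·count/total, rounded half-up to one decimal place."""
    if total <= 0:
        raise DataError("total must be positive")
    if not 0 <= count <= total:
        raise DataError("count must be in [0, total]")
    q = decimal.Decimal(100 * count) / decimal.Decimal(total)
    return float(q.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def format_percent(pct: float) -> str:
    """Display style: integer when exact ('9%'), else one decimal ('16.3%')."""
    return f"{pct:g}%" if float(pct) == int(pct) else f"{pct:.1f}%"


# ---------------------------------------------------------------------------
# on-disk formats: CSV + JSON sidecar, and an HDF5 container


def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(csv_path.suffix + ".json")


def write_traces(t: TraceMatrix, path: str | Path) -> None:
    """Write a trace matrix as CSV (rows = neurons, header = frame index)
    with a JSON metadata sidecar at ``<path>.json``."""
    path = Path(path)
    df = pd.DataFrame(t.activity, columns=[str(f) for f in range(t.n_frames)])
    df.to_csv(path, index=False)
    meta = {
        "session_id": t.session_id,
        "frame_rate_hz": t.frame_rate_hz,
        "neuron_ids": list(t.neuron_ids),
        "normalization": t.normalization,
        "constant_neurons": sorted(t.constant_neurons),
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def load_traces(path: str | Path, format: str = "csv") -> TraceMatrix:
    """Load a trace matrix from ``csv`` (+ JSON sidecar) or ``hdf5``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "hdf5":
        traces, _, _ = load_container(path)
        return traces
    if format != "csv":
        raise FormatError(f"unknown format {format!r}")
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed metadata {meta_path}: {exc}") from exc
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"malformed CSV {path}: {exc}") from exc
    act = df.to_numpy(dtype=float)
    if np.isnan(act).any():
        i, j = np.argwhere(np.isnan(act))[0]
        raise DataError(f"NaN at row {i}, frame column {df.columns[j]!r} in {path}")
    for key in ("session_id", "frame_rate_hz", "neuron_ids"):
        if key not in meta:
            raise FormatError(f"metadata {meta_path} missing field {key!r}")
    return TraceMatrix(
        session_id=meta["session_id"],
        neuron_ids=tuple(meta["neuron_ids"]),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        activity=act,
        normalization=meta.get("normalization", "raw_nonneg"),
        constant_neurons=frozenset(meta.get("constant_neurons", ())),
    )


def write_bouts(b: BoutList, path: str | Path) -> None:
    df = pd.DataFrame(b.intervals, columns=["start_s", "end_s"])
    df.to_csv(path, index=False)


def load_bouts(path: str | Path, session_duration_s: float) -> BoutList:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"malformed bout CSV {path}: {exc}") from exc
    if list(df.columns) != ["start_s", "end_s"]:
        raise FormatError(
            f"bout CSV {path} must have columns start_s,end_s; got {list(df.columns)}"
        )
    intervals = tuple(zip(df["start_s"].astype(float), df["end_s"].astype(float)))
    return BoutList(intervals=intervals, session_duration_s=session_duration_s)


def save_container(
    path: str | Path,
    traces: TraceMatrix | Sequence[TraceMatrix],
    bouts: Mapping[str, BoutList] | None = None,
    identity: Mapping[str, IdentityMap] | None = None,
) -> None:
    """Write sessions into one hierarchical HDF5 container.

    Layout: ``/traces/<session>`` (dataset ``activity``, attrs + ``neuron_ids``),
    ``/bouts/<session>`` (n×2 dataset, attr ``session_duration_s``),
    ``/identity/<name>`` (two string datasets ``a`` and ``b``).
    """
    import h5py

    if isinstance(traces, TraceMatrix):
        traces = [traces]
    with h5py.File(path, "w") as f:
        g = f.create_group("traces")
        for t in traces:
            sg = g.create_group(t.session_id)
            sg.create_dataset("activity", data=t.activity)
            sg.create_dataset(
                "neuron_ids", data=np.array(t.neuron_ids, dtype=h5py.string_dtype())
            )
            sg.attrs["frame_rate_hz"] = t.frame_rate_hz
            sg.attrs["normalization"] = t.normalization
            sg.attrs["constant_neurons"] = json.dumps(sorted(t.constant_neurons))
        if bouts:
            g = f.create_group("bouts")
            for sid, b in bouts.items():
                d = g.create_dataset(
                    sid, data=np.array(b.intervals, dtype=float).reshape(-1, 2)
                )
                d.attrs["session_duration_s"] = b.session_duration_s
        if identity:
            g = f.create_group("identity")
            for name, m in identity.items():
                mg = g.create_group(name)
                keys = sorted(m.pairs)
                mg.create_dataset("a", data=np.array(keys, dtype=h5py.string_dtype()))
                mg.create_dataset(
                    "b",
                    data=np.array([m.pairs[k] for k in keys], dtype=h5py.string_dtype()),
                )


def load_container(
    path: str | Path,
) -> tuple[
    TraceMatrix | dict[str, TraceMatrix],
    dict[str, BoutList],
    dict[str, IdentityMap],
]:
    """Read an HDF5 container written by :func:`save_container`.

    Returns ``(traces, bouts, identity)``; ``traces`` is a single TraceMatrix
    when the container holds exactly one session, else a dict by session id.
    """
    import h5py

    traces: dict[str, TraceMatrix] = {}
    bouts: dict[str, BoutList] = {}
    identity: dict[str, IdentityMap] = {}
    with h5py.File(path, "r") as f:
        if "traces" not in f:
            raise FormatError(f"{path} has no /traces group")
        for sid, sg in f["traces"].items():
            traces[sid] = TraceMatrix(
                session_id=sid,
                neuron_ids=tuple(x.decode() for x in sg["neuron_ids"][()]),
                frame_rate_hz=float(sg.attrs["frame_rate_hz"]),
                activity=sg["activity"][()],
                normalization=str(sg.attrs["normalization"]),
                constant_neurons=frozenset(
                    json.loads(sg.attrs.get("constant_neurons", "[]"))
                ),
            )
        for sid, d in f.get("bouts", {}).items():
            bouts[sid] = BoutList(
                intervals=tuple(map(tuple, d[()])),
                session_duration_s=float(d.attrs["session_duration_s"]),
            )
        for name, mg in f.get("identity", {}).items():
            identity[name] = IdentityMap(
                pairs=dict(
                    zip(
                        (x.decode() for x in mg["a"][()]),
                        (x.decode() for x in mg["b"][()]),
                    )
                )
            )
    if len(traces) == 1:
        return next(iter(traces.values())), bouts, identity
    return traces, bouts, identity
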