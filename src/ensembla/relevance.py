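"""Single-neuron behavior-relevance classification.

Each neuron's raw non-negative calcium trace is compared with the binary
behavior vector by cosine similarity R (which lies in [0, 1] for
non-negative inputs).  A permutation null is built by circularly shifting
the trace by random offsets — a shuffle that preserves the trace's
autocorrelation, so the calcium kernel itself cannot inflate significance —
and the neuron is called *positive* when R strictly exceeds the null's 95th
percentile, *negative* when strictly below the 5th, and *irrelevant*
otherwise.  A plain frame-permutation shuffle is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import BehaviorVector, DataError, IdentityMap, TraceMatrix

__all__ = [
    "RelevanceCall",
    "RelevanceSummary",
    "cosine_similarity",
    "shuffled_null",
    "classify_neurons",
    "relevance_ratios",
    "mean_bout_activity",
    "session_overlap_table",
]

LABELS = ("positive", "negative", "irrelevant")


@dataclass(frozen=True)
class RelevanceCall:
    """Classification of one neuron against one behavior vector."""

    neuron_id: str
    R: float  # raw cosine similarity; NaN for constant traces
    null_p05: float
    null_p95: float
    label: str
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise DataError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class RelevanceSummary:
    """Per-label counts and percentages over the registered population."""

    counts: dict[str, int]
    ratios_pct: dict[str, float]
    total_registered: int


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """(a·b)/(‖a‖‖b‖); in [0, 1] when both vectors are non-negative."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("vectors must be 1-D and of equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("cosine similarity undefined for a zero-norm vector")
    return float(a @ b / (na * nb))


def _all_shift_cosines(trace: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cosine similarity of every circular shift of ``trace`` with ``b``.

    Entry k is cos(roll(trace, k), b), computed in one pass via FFT
    cross-correlation; circular shifting leaves ‖trace‖ unchanged.
    """
    n = trace.shape[0]
    dots = np.fft.irfft(np.conj(np.fft.rfft(trace)) * np.fft.rfft(b), n)
    return dots / (np.linalg.norm(trace) * np.linalg.norm(b))


def shuffled_null(
    trace: np.ndarray,
    b: BehaviorVector,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    mode: str = "circular",
) -> dict:
    """Permutation null of the trace–behavior cosine similarity.

    ``mode='circular'`` (default) draws ``n_perm`` uniform offsets in
    [1, n_frames−1] and circularly shifts the trace; ``mode='permutation'``
    shuffles frames outright.  Returns the raw statistic, the empirical
    5th/95th percentiles (linear interpolation), and the null sample.
    """
    trace = np.asarray(trace, dtype=float)
    bv = b.values.astype(float)
    if trace.shape[0] != b.n_frames:
        raise DataError("trace and behavior vector lengths differ")
    if n_perm < 100:
        raise ValueError("n_perm must be ≥ 100 for stable tail percentiles")
    if np.ptp(trace) == 0:
        raise DataError("constant trace: shuffled null is degenerate")
    if b.is_constant:
        raise DataError("constant behavior vector: cosine null is degenerate")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = trace.shape[0]
    raw = cosine_similarity(trace, bv)
    if mode == "circular":
        all_cos = _all_shift_cosines(trace, bv)
        offsets = rng.integers(1, n, size=n_perm)
        null = all_cos[offsets]
    elif mode == "permutation":
        norm = np.linalg.norm(trace) * np.linalg.norm(bv)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        null = (trace[idx] @ bv) / norm
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return {
        "raw": raw,
        "null_p05": float(np.percentile(null, 5)),
        "null_p95": float(np.percentile(null, 95)),
        "null": null,
    }


def classify_neurons(
    t: TraceMatrix,
    b: BehaviorVector,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "circular",
) -> list[RelevanceCall]:
    """Label every neuron positive / negative / irrelevant.

    Strict inequalities: R exactly at a percentile is irrelevant.  Constant
    traces are labeled irrelevant with R = NaN.  Cosine similarity is
    computed on the raw non-negative traces.
    """
    if t.normalization != "raw_nonneg":
        raise DataError("relevance classification runs on raw non-negative traces")
    if t.n_frames != b.n_frames:
        raise DataError("trace matrix and behavior vector lengths differ")
    if b.is_constant:
        raise DataError("behavior vector is constant")
    rng = np.random.default_rng(seed)
    calls: list[RelevanceCall] = []
    for i, nid in enumerate(t.neuron_ids):
        trace = t.activity[i]
        if np.ptp(trace) == 0:
            calls.append(
                RelevanceCall(nid, np.nan, np.nan, np.nan, "irrelevant", n_perm)
            )
            continue
        res = shuffled_null(trace, b, n_perm=n_perm, seed=rng, mode=mode)
        if res["raw"] > res["null_p95"]:
            label = "positive"
        elif res["raw"] < res["null_p05"]:
            label = "negative"
        else:
            label = "irrelevant"
        calls.append(
            RelevanceCall(
                nid, res["raw"], res["null_p05"], res["null_p95"], label, n_perm
            )
        )
    return calls


def relevance_ratios(
    calls: list[RelevanceCall], total_registered: int
) -> RelevanceSummary:
    """Per-label counts normalized against the registered population size
    (which may exceed the number classified in this session)."""
    if total_registered <= 0:
        raise DataError("total_registered must be positive")
    if total_registered < len(calls):
        raise DataError("total_registered smaller than the number of calls")
    counts = {lab: sum(c.label == lab for c in calls) for lab in LABELS}
    from .traces import percent_of_total

    ratios = {
        lab: percent_of_total(counts[lab], total_registered) for lab in LABELS
    }
    return RelevanceSummary(
        counts=counts, ratios_pct=ratios, total_registered=total_registered
    )


def mean_bout_activity(
    t: TraceMatrix, b: BehaviorVector, subset: set[str] | list[str]
) -> dict:
    """Mean z-scored activity during behavior bouts for a neuron subset.

    Returns per-neuron means plus the group mean ± SEM across neurons.
    """
    subset = [str(s) for s in subset]
    if not subset:
        raise DataError("subset must be non-empty")
    if b.values.sum() == 0:
        raise DataError("no bout frames: mean bout activity undefined")
    if t.n_frames != b.n_frames:
        raise DataError("trace matrix and behavior vector lengths differ")
    mask = b.values.astype(bool)
    per_neuron = pd.Series(
        {nid: float(t.row(nid)[mask].mean()) for nid in subset}, name="mean_bout"
    )
    sem = (
        float(per_neuron.std(ddof=1) / np.sqrt(len(per_neuron)))
        if len(per_neuron) > 1
        else np.nan
    )
    return {
        "per_neuron": per_neuron,
        "group_mean": float(per_neuron.mean()),
        "group_sem": sem,
    }


def session_overlap_table(
    calls_per_session: dict[str, list[RelevanceCall]],
    maps: dict[tuple[str, str], IdentityMap],
) -> dict:
    """Track registered neurons across sessions.

    ``maps`` gives identity maps keyed by (reference_session, other_session);
    each neuron of the reference session is followed through every map.
    Returns a long-format table (registered id × session × label) and the
    pairwise counts of neurons responsive (non-irrelevant) in both sessions
    of a pair — the data underlying a connectogram.
    """
    sessions = sorted(calls_per_session)
    labels = {
        s: {c.neuron_id: c.label for c in calls_per_session[s]} for s in sessions
    }
    if not maps and len(sessions) > 1:
        raise DataError("identity maps required for multi-session overlap")
    ref = sessions[0]
    for (a, _b), m in maps.items():
        if a != ref:
            raise DataError(
                f"identity maps must be keyed from the reference session {ref!r}"
            )
        for ka in m.pairs:
            if ka not in labels[ref]:
                raise DataError(f"mapped id {ka!r} missing from session {ref!r}")
    rows = []
    for rid in labels[ref]:
        rows.append({"registered_id": rid, "session": ref, "label": labels[ref][rid]})
        for (_, other), m in maps.items():
            oid = m.pairs.get(rid)
            if oid is not None and oid in labels[other]:
                rows.append(
                    {
                        "registered_id": rid,
                        "session": other,
                        "label": labels[other][oid],
                    }
                )
    table = pd.DataFrame(rows, columns=["registered_id", "session", "label"])
    responsive = {
        s: set(
            table.loc[
                (table.session == s) & (table.label != "irrelevant"),
                "registered_id",
            ]
        )
        for s in sessions
    }
    shared = {
        (s1, s2): len(responsive[s1] & responsive[s2])
        for i, s1 in enumerate(sessions)
        for s2 in sessions[i + 1 :]
    }
    return {"table": table, "shared_responsive": shared}
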