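"""Surrogate-based functional-network inference.

Pairwise neuronal similarity is the cosine of the two raw traces.  The null
for each pair comes from phase-randomized surrogates: Fourier phases are
replaced by i.i.d. uniform draws while the amplitude spectrum (hence power,
mean and autocorrelation) is preserved exactly.  A pair is linked when its
raw similarity strictly exceeds the surrogate distribution's 99.17th
percentile.  Degree centrality (links / (n−1)) summarizes each neuron's
embedding in the resulting graph.

To keep the surrogate count at 10,000 per pair without 10,000 fresh
transforms per pair, S surrogates are generated once per neuron (default
S = 100) and crossed to give S² pair similarities — the same null law,
at ~n·S transforms instead of n²·10,000.  A per-pair mode regenerating
fresh surrogates for every pair is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .traces import DataError, TraceMatrix

__all__ = [
    "FunctionalNetwork",
    "phase_randomize",
    "pair_significance",
    "build_network",
    "degree_centrality",
    "subgroup_centrality",
]

DEFAULT_THRESHOLD_PCT = 99.17
DEFAULT_N_SURROGATES = 10_000


@dataclass(frozen=True)
class FunctionalNetwork:
    """Similarity matrix, surrogate-thresholded adjacency, and centrality."""

    neuron_ids: tuple[str, ...]
    similarity: np.ndarray  # symmetric, diagonal 1
    adjacency: np.ndarray  # symmetric binary, zero diagonal
    threshold_percentile: float = DEFAULT_THRESHOLD_PCT
    n_surrogates: int = DEFAULT_N_SURROGATES
    thresholds: np.ndarray | None = None  # per-pair surrogate percentile

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or a.diagonal().any():
            raise DataError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise DataError("adjacency must be binary")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def degree_centrality(self) -> pd.Series:
        return degree_centrality(self)

    @property
    def edge_density(self) -> float:
        n = self.n_neurons
        return float(self.adjacency.sum() / (n * (n - 1)))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.neuron_ids)
        for i, j in zip(*np.triu_indices(self.n_neurons, k=1)):
            if self.adjacency[i, j]:
                g.add_edge(
                    self.neuron_ids[i],
                    self.neuron_ids[j],
                    similarity=float(self.similarity[i, j]),
                )
        return g


def phase_randomize(
    trace: np.ndarray, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Phase-randomized surrogate(s) of a real signal.

    The DFT phases of all non-DC, non-Nyquist bins are replaced by i.i.d.
    uniform(0, 2π) draws (Hermitian symmetry enforced by construction via
    the real inverse transform); amplitudes are untouched, so the surrogate
    has exactly the original amplitude spectrum and mean.  ``size`` returns
    a [size × n] stack of independent surrogates.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.shape[0] < 4:
        raise DataError("phase randomization needs a 1-D signal of length ≥ 4")
    if not np.isfinite(trace).all():
        raise DataError("non-finite values in signal")
    n = trace.shape[0]
    spec = np.fft.rfft(trace)
    amp = np.abs(spec)
    n_draw = 1 if size is None else size
    # randomizable bins: exclude DC (0) and, for even n, the Nyquist bin
    lo, hi = 1, spec.shape[0] - 1 if n % 2 == 0 else spec.shape[0]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_draw, hi - lo))
    surr_spec = np.tile(spec, (n_draw, 1)).astype(complex)
    surr_spec[:, lo:hi] = amp[lo:hi] * np.exp(1j * phases)
    out = np.fft.irfft(surr_spec, n, axis=1)
    return out[0] if size is None else out


def _cosine_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    nx_ = np.linalg.norm(x, axis=1, keepdims=True)
    ny_ = np.linalg.norm(y, axis=1, keepdims=True)
    return (x @ y.T) / (nx_ @ ny_.T)


def pair_significance(
    a: np.ndarray,
    b: np.ndarray,
    n_surr: int = DEFAULT_N_SURROGATES,
    threshold_percentile: float = DEFAULT_THRESHOLD_PCT,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Surrogate test for one pair of traces.

    Both traces are independently phase-randomized ``√n_surr`` times and
    crossed to give ``n_surr`` surrogate cosine similarities; the pair is
    linked iff the raw similarity strictly exceeds the
    ``threshold_percentile`` of that sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        raise DataError("zero-norm trace")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    s = max(2, int(round(np.sqrt(n_surr))))
    sa = phase_randomize(a, rng, size=s)
    sb = phase_randomize(b, rng, size=s)
    null = _cosine_matrix(sa, sb).ravel()
    raw = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    thr = float(np.percentile(null, threshold_percentile))
    return {"similarity": raw, "threshold": thr, "is_link": raw > thr, "null": null}


def build_network(
    t: TraceMatrix,
    n_surr: int = DEFAULT_N_SURROGATES,
    threshold_percentile: float = DEFAULT_THRESHOLD_PCT,
    seed: int = 0,
    per_pair_surrogates: bool = False,
) -> FunctionalNetwork:
    """Apply the surrogate pair test to all unordered neuron pairs.

    Default mode draws S = √n_surr surrogates per neuron once and crosses
    them per pair; ``per_pair_surrogates`` regenerates fresh surrogates for
    every pair (slower, same null law).
    """
    if t.n_neurons < 2:
        raise DataError("need at least 2 neurons to build a network")
    rng = np.random.default_rng(seed)
    n = t.n_neurons
    act = t.activity
    norms = np.linalg.norm(act, axis=1)
    if (norms == 0).any():
        raise DataError("zero-norm trace in matrix")
    sim = (act @ act.T) / np.outer(norms, norms)
    adj = np.zeros((n, n), dtype=np.int8)
    thresholds = np.zeros((n, n))
    if per_pair_surrogates:
        for i in range(n):
            for j in range(i + 1, n):
                res = pair_significance(
                    act[i], act[j], n_surr, threshold_percentile, rng
                )
                thresholds[i, j] = thresholds[j, i] = res["threshold"]
                adj[i, j] = adj[j, i] = int(res["is_link"])
    else:
        s = max(2, int(round(np.sqrt(n_surr))))
        surr = np.empty((n, s, t.n_frames))
        for i in range(n):
            surr[i] = phase_randomize(act[i], rng, size=s)
        surr_n = surr / np.linalg.norm(surr, axis=2, keepdims=True)
        for i in range(n):
            for j in range(i + 1, n):
                null = (surr_n[i] @ surr_n[j].T).ravel()
                thr = float(np.percentile(null, threshold_percentile))
                thresholds[i, j] = thresholds[j, i] = thr
                adj[i, j] = adj[j, i] = int(sim[i, j] > thr)
    return FunctionalNetwork(
        neuron_ids=t.neuron_ids,
        similarity=sim,
        adjacency=adj,
        threshold_percentile=threshold_percentile,
        n_surrogates=n_surr,
        thresholds=thresholds,
    )


def degree_centrality(net: FunctionalNetwork) -> pd.Series:
    """Per-neuron degree centrality: links / (n − 1), via networkx."""
    if net.n_neurons < 2:
        raise DataError("degree centrality undefined for n < 2")
    dc = nx.degree_centrality(net.to_graph())
    return pd.Series(
        [dc[i] for i in net.neuron_ids], index=list(net.neuron_ids), name="degree_centrality"
    )


def subgroup_centrality(net: FunctionalNetwork, calls) -> dict:
    """Degree centrality partitioned into all / behavior-linked / irrelevant.

    Behavior-linked covers both positively and negatively correlated
    neurons.  Empty groups are reported with NaN means, not errors.
    """
    labels = {c.neuron_id: c.label for c in calls}
    missing = [i for i in net.neuron_ids if i not in labels]
    if missing:
        raise DataError(f"relevance calls missing for neurons {missing[:3]}...")
    dc = degree_centrality(net)
    linked = [i for i in net.neuron_ids if labels[i] in ("positive", "negative")]
    irrel = [i for i in net.neuron_ids if labels[i] == "irrelevant"]

    def _stats(ids: list[str]) -> dict:
        if not ids:
            return {"n": 0, "mean": np.nan, "sem": np.nan, "values": pd.Series(dtype=float)}
        v = dc[ids]
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        return {"n": len(v), "mean": float(v.mean()), "sem": sem, "values": v}

    return {
        "all": _stats(list(net.neuron_ids)),
        "behavior_linked": _stats(linked),
        "irrelevant": _stats(irrel),
    }
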