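"""Neuronal ensemble detection and ensemble-level correlation analysis.

Neurons are clustered on their z-scored traces with k-means (Euclidean
distance; for unit-variance rows this is monotone in 1 − Pearson r), the
number of ensembles is gauged from the within-cluster sum of squares (WCSS)
curve by the elbow (maximum discrete second difference), and Pearson
correlations link ensemble mean activity to the binary behavior vector and
individual neurons to their own ensemble mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .traces import BehaviorVector, DataError, StateError, TraceMatrix

__all__ = [
    "EnsembleModel",
    "CorrelationSet",
    "wcss_curve",
    "select_k",
    "cluster_neurons",
    "ensemble_behavior_correlation",
    "neuron_ensemble_correlation",
    "compare_correlation_cdfs",
    "cross_session_r_scatter",
]

# relative second-difference floor below which a WCSS curve is called
# structureless and k = 1 is returned
FLAT_CURVE_REL_TOL = 0.01


def _require_zscore(t: TraceMatrix) -> None:
    if t.normalization != "zscore":
        raise StateError("ensemble analysis expects z-scored traces")


@dataclass(frozen=True)
class EnsembleModel:
    """k-means ensemble assignment for one session."""

    k: int
    wcss_curve: dict[int, float]
    labels: np.ndarray  # ensemble index per neuron, values in [0, k)
    ensemble_means: np.ndarray  # [k × n_frames] mean z-scored trace
    neuron_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.min() < 0 or labels.max() >= self.k:
            raise DataError("labels must lie in [0, k)")
        if self.ensemble_means.shape[0] != self.k:
            raise DataError("ensemble_means must have k rows")

    def members(self, ensemble: int) -> list[str]:
        return [i for i, l in zip(self.neuron_ids, self.labels) if l == ensemble]


@dataclass(frozen=True)
class CorrelationSet:
    """Pearson correlations attached to an EnsembleModel.

    ``neuron_r`` is each neuron's correlation with its own ensemble mean
    (NaN for flagged constant rows); ``ensemble_behavior_r`` is each
    ensemble mean's correlation with the behavior vector.
    """

    neuron_r: pd.Series  # indexed by neuron_id
    ensemble_behavior_r: np.ndarray | None = None
    flagged: frozenset[str] = frozenset()


def wcss_curve(
    t: TraceMatrix,
    k_range: range | list[int] = range(1, 7),
    seed: int = 0,
    n_restarts: int = 20,
) -> dict[int, float]:
    """Best-of-restarts k-means WCSS for each k (the k-means objective:
    summed squared Euclidean distance of each neuron's trace to its
    assigned centroid)."""
    _require_zscore(t)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > t.n_neurons:
        raise ValueError(
            f"k_range must lie within [1, n_neurons={t.n_neurons}], got {ks}"
        )
    curve: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(t.activity)
        curve[k] = float(km.inertia_)
    return curve


def select_k(curve: dict[int, float]) -> int:
    """Elbow rule: the interior k maximizing the discrete second difference
    WCSS(k−1) − 2·WCSS(k) + WCSS(k+1); ties broken toward smaller k.

    A curve with no elbow (all second differences below 1% of the
    smallest-k WCSS) yields 1 with a warning.
    """
    ks = sorted(curve)
    if len(ks) < 3:
        raise ValueError("need WCSS at ≥3 values of k to locate an elbow")
    wcss = np.array([curve[k] for k in ks])
    if np.any(np.diff(wcss) > 1e-9 * max(1.0, wcss[0])):
        warnings.warn("WCSS curve is not non-increasing; clustering may be unstable")
    d2 = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]  # second difference at interior ks
    best = int(np.argmax(d2))
    if d2[best] <= FLAT_CURVE_REL_TOL * max(wcss[0], 1e-300):
        warnings.warn("WCSS curve shows no elbow; returning k=1")
        return 1
    return ks[1 + best]


def cluster_neurons(
    t: TraceMatrix, k: int, seed: int = 0, n_restarts: int = 20
) -> EnsembleModel:
    """Assign neurons to k ensembles from the best-WCSS k-means restart."""
    _require_zscore(t)
    if not 1 <= k <= t.n_neurons:
        raise ValueError(f"k must be in [1, n_neurons={t.n_neurons}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(t.activity)
    if len(np.unique(labels)) < k:
        raise RuntimeError(f"k-means left an empty cluster after {n_restarts} restarts")
    means = np.stack([t.activity[labels == j].mean(axis=0) for j in range(k)])
    return EnsembleModel(
        k=k,
        wcss_curve={k: float(km.inertia_)},
        labels=labels,
        ensemble_means=means,
        neuron_ids=t.neuron_ids,
    )


def ensemble_behavior_correlation(
    m: EnsembleModel, b: BehaviorVector
) -> np.ndarray:
    """Pearson r of each ensemble mean trace with the binary behavior vector."""
    if m.ensemble_means.shape[1] != b.n_frames:
        raise DataError("ensemble means and behavior vector lengths differ")
    if b.is_constant:
        raise DataError("behavior vector is constant; correlation undefined")
    bv = b.values.astype(float)
    return np.array(
        [stats.pearsonr(row, bv).statistic for row in m.ensemble_means]
    )


def neuron_ensemble_correlation(
    t: TraceMatrix,
    m: EnsembleModel,
    exclude_self: bool = False,
) -> CorrelationSet:
    """Pearson r of each neuron with the mean trace of its own ensemble.

    The neuron's own trace is included in the ensemble mean by default;
    singleton ensembles then give r = 1 by self-correlation and are flagged,
    as are constant rows (r reported as NaN).  ``exclude_self`` computes a
    leave-one-out ensemble mean instead.
    """
    _require_zscore(t)
    if len(m.labels) != t.n_neurons:
        raise DataError("model labels do not cover the trace matrix")
    rs: dict[str, float] = {}
    flagged: set[str] = set()
    counts = np.bincount(m.labels, minlength=m.k)
    sums = np.zeros((m.k, t.n_frames))
    for j in range(m.k):
        sums[j] = t.activity[m.labels == j].sum(axis=0)
    for i, nid in enumerate(t.neuron_ids):
        lab = m.labels[i]
        row = t.activity[i]
        if nid in t.constant_neurons:
            rs[nid] = np.nan
            flagged.add(nid)
            continue
        if exclude_self:
            if counts[lab] < 2:
                rs[nid] = np.nan
                flagged.add(nid)
                continue
            ref = (sums[lab] - row) / (counts[lab] - 1)
        else:
            ref = sums[lab] / counts[lab]
            if counts[lab] == 1:
                flagged.add(nid)  # singleton: r = 1 by construction
        if np.std(ref) == 0:
            rs[nid] = np.nan
            flagged.add(nid)
            continue
        rs[nid] = float(stats.pearsonr(row, ref).statistic)
    return CorrelationSet(
        neuron_r=pd.Series(rs, name="r"), flagged=frozenset(flagged)
    )


def compare_correlation_cdfs(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of correlation samples
    (asymptotic p).  Returns (D, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(a.size, b.size) < 3:
        warnings.warn("KS comparison on fewer than 3 values is uninformative")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def cross_session_r_scatter(
    pairs: np.ndarray | list[tuple[float, float]]
) -> tuple[float, float]:
    """Pearson correlation across dual-recorded neurons of their
    neuron–ensemble r in session 1 vs session 2.  Returns (r, p)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need ≥3 (r_session1, r_session2) pairs")
    res = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(res.statistic), float(res.pvalue)
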