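"""End-to-end orchestration: z-score → ensembles → relevance → network.

Runs every stage per session, plus cross-session analyses where identity
maps exist, and writes CSV/JSON outputs with a run manifest recording every
seed and parameter so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensembles as ens
from . import funcnet, relevance
from .traces import (
    BoutList,
    IdentityMap,
    TraceMatrix,
    load_container,
    make_behavior_vector,
    zscore_traces,
)

log = logging.getLogger("ensembla")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of a full pipeline run."""

    container: str
    out_dir: str
    n_permutations: int = 1000
    n_surrogates: int = 10_000
    threshold_percentile: float = 99.17
    k_override: int | None = None  # None → WCSS elbow selection
    k_range: tuple[int, int] = (1, 6)
    n_restarts: int = 20
    seed: int = 0
    session_roster: tuple[str, ...] = ()  # empty → all sessions in container

    def __post_init__(self) -> None:
        if self.n_permutations < 100 or self.n_surrogates < 100:
            raise ValueError("permutation/surrogate counts must be ≥ 100")
        if not 50.0 < self.threshold_percentile < 100.0:
            raise ValueError("threshold_percentile must lie in (50, 100)")
        if self.k_override is not None and self.k_override < 1:
            raise ValueError("k override must be ≥ 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for key in ("k_range", "session_roster"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _analyze_session(
    sid: str,
    raw: TraceMatrix,
    bouts: BoutList,
    cfg: PipelineConfig,
    out: Path,
) -> dict:
    z = zscore_traces(raw)
    b = make_behavior_vector(bouts, raw.frame_rate_hz, raw.n_frames)
    result: dict = {"session": sid, "n_neurons": raw.n_neurons}
    # ensembles
    lo, hi = cfg.k_range
    hi = min(hi, raw.n_neurons)
    curve = ens.wcss_curve(z, range(lo, hi + 1), seed=cfg.seed, n_restarts=cfg.n_restarts)
    k = cfg.k_override if cfg.k_override is not None else ens.select_k(curve)
    model = ens.cluster_neurons(z, k, seed=cfg.seed, n_restarts=cfg.n_restarts)
    pd.Series(curve, name="wcss").rename_axis("k").to_csv(out / f"{sid}_wcss.csv")
    pd.DataFrame(
        {"neuron_id": z.neuron_ids, "ensemble": model.labels}
    ).to_csv(out / f"{sid}_ensembles.csv", index=False)
    behav_r = (
        None if b.is_constant else ens.ensemble_behavior_correlation(model, b)
    )
    corr = ens.neuron_ensemble_correlation(z, model)
    corr.neuron_r.rename_axis("neuron_id").to_csv(out / f"{sid}_neuron_ensemble_r.csv")
    result["k"] = k
    result["ensemble_behavior_r"] = (
        None if behav_r is None else [float(r) for r in behav_r]
    )
    # relevance
    if b.is_constant:
        log.warning("session %s: constant behavior vector, relevance skipped", sid)
        calls = None
    else:
        calls = relevance.classify_neurons(
            raw, b, n_perm=cfg.n_permutations, seed=cfg.seed
        )
        pd.DataFrame(
            [
                {
                    "neuron_id": c.neuron_id,
                    "R": c.R,
                    "null_p05": c.null_p05,
                    "null_p95": c.null_p95,
                    "label": c.label,
                }
                for c in calls
            ]
        ).to_csv(out / f"{sid}_relevance.csv", index=False)
        summary = relevance.relevance_ratios(calls, raw.n_neurons)
        (out / f"{sid}_relevance_summary.json").write_text(
            json.dumps(
                {
                    "counts": summary.counts,
                    "ratios_pct": summary.ratios_pct,
                    "total_registered": summary.total_registered,
                },
                indent=1,
            )
        )
        result["relevance_counts"] = summary.counts
    # network
    net = funcnet.build_network(
        raw,
        n_surr=cfg.n_surrogates,
        threshold_percentile=cfg.threshold_percentile,
        seed=cfg.seed,
    )
    dc = net.degree_centrality
    dc.rename_axis("neuron_id").to_csv(out / f"{sid}_degree_centrality.csv")
    edges = [
        {
            "i": net.neuron_ids[i],
            "j": net.neuron_ids[j],
            "similarity": float(net.similarity[i, j]),
            "threshold": float(net.thresholds[i, j]),
        }
        for i, j in zip(*np.triu_indices(net.n_neurons, k=1))
        if net.adjacency[i, j]
    ]
    pd.DataFrame(edges, columns=["i", "j", "similarity", "threshold"]).to_csv(
        out / f"{sid}_edges.csv", index=False
    )
    result["edge_density"] = net.edge_density
    result["mean_degree_centrality"] = float(dc.mean())
    result["calls"] = calls
    result["corr"] = corr
    return result


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on every session of the container; returns and
    writes a manifest of stages completed, parameters and outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces, bouts, identity = load_container(cfg.container)
    if isinstance(traces, TraceMatrix):
        traces = {traces.session_id: traces}
    roster = list(cfg.session_roster) or sorted(traces)
    missing = [s for s in roster if s not in traces]
    if missing:
        raise KeyError(f"sessions {missing} not in container")
    manifest: dict = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "sessions": {},
        "cross_session": {},
        "stages_completed": [],
    }
    per_session: dict[str, dict] = {}
    for sid in roster:
        if sid not in bouts:
            raise KeyError(f"no bouts recorded for session {sid!r}")
        log.info("analyzing session %s", sid)
        res = _analyze_session(sid, traces[sid], bouts[sid], cfg, out)
        per_session[sid] = res
        manifest["sessions"][sid] = {
            k: v for k, v in res.items() if k not in ("calls", "corr")
        }
        manifest["stages_completed"].append(sid)
    # cross-session: neuron–ensemble r scatter over dual-recorded neurons
    for name, imap in identity.items():
        sa, _, sb = name.partition("->")
        if sa not in per_session or sb not in per_session:
            log.warning("identity map %s references unanalyzed sessions; skipped", name)
            continue
        ra = per_session[sa]["corr"].neuron_r
        rb = per_session[sb]["corr"].neuron_r
        pairs = [
            (ra[ka], rb[kb])
            for ka, kb in imap.pairs.items()
            if ka in ra.index and kb in rb.index
            and np.isfinite(ra[ka]) and np.isfinite(rb[kb])
        ]
        if len(pairs) < 3:
            log.warning("identity map %s: <3 usable pairs; scatter skipped", name)
            continue
        r, p = ens.cross_session_r_scatter(pairs)
        manifest["cross_session"][name] = {"n_pairs": len(pairs), "r": r, "p": p}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
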