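"""Seeded generator of miniscope-like calcium-imaging sessions.

Emulates GCaMP-style recordings at 10 Hz: per-neuron binary event trains
convolved with an exponential decay kernel plus Gaussian noise, rectified at
zero.  Behavior bouts follow an alternating renewal process; three neuron
classes respond to them differently (positive: elevated event rate inside
bouts, negative: elevated outside, irrelevant: constant rate), and ensembles
of neurons share latent drive events that make their traces co-fluctuate.
Paired sessions with partial neuron overlap support dual-recorded analyses.

Ground truth (class, ensemble, identity) is returned with every session so
the detection stages can be scored by parameter recovery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .traces import BoutList, TraceMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_bouts",
    "simulate_session",
    "simulate_paired_sessions",
    "two_ensemble_config",
    "hyperconnectivity_config",
    "irrelevant_only_config",
]

CLASSES = ("positive", "negative", "irrelevant")
MIN_BOUT_S = 0.5  # shortest scoreable behavior bout


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated session.

    Defaults describe a 10-minute session at 10 Hz (6,000 frames) with
    social-bout statistics in the range of scored rodent interactions
    (mean bout 3 s, mean gap 12 s → ~20% of time in bouts).  Event rates
    are per-second Bernoulli-thinned per frame; ``kernel_tau_s`` is the
    calcium indicator decay constant (1 s, GCaMP-like at 10 Hz).
    """

    n_neurons: int = 60
    n_frames: int = 6000
    frame_rate_hz: float = 10.0
    mean_bout_s: float = 3.0
    mean_gap_s: float = 12.0
    class_mix: tuple[float, float, float] = (0.3, 0.2, 0.5)
    rate_on_hz: float = 2.0
    rate_off_hz: float = 0.2
    rate_base_hz: float = 0.5
    n_ensembles: int = 2
    ensemble_drive_rate_hz: float = 0.3
    participation_p: float = 0.6
    ensemble_classes: tuple[str, ...] = CLASSES
    kernel_tau_s: float = 1.0
    noise_sd: float = 0.1
    cross_session_overlap_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_frames < 2:
            raise ValueError("n_neurons and n_frames must be positive")
        if self.frame_rate_hz <= 0 or self.kernel_tau_s <= 0:
            raise ValueError("frame_rate_hz and kernel_tau_s must be positive")
        if self.mean_bout_s <= 0 or self.mean_gap_s <= 0:
            raise ValueError("mean bout/gap durations must be positive")
        if any(r < 0 for r in (self.rate_on_hz, self.rate_off_hz, self.rate_base_hz)):
            raise ValueError("event rates must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        mix = self.class_mix
        if len(mix) != 3 or any(f < 0 for f in mix) or abs(sum(mix) - 1) > 1e-9:
            raise ValueError("class_mix must be 3 non-negative fractions summing to 1")
        if not 0 <= self.participation_p <= 1:
            raise ValueError("participation_p must be a probability")
        if not 0 <= self.cross_session_overlap_p <= 1:
            raise ValueError("cross_session_overlap_p must be a probability")
        if self.n_ensembles < 0 or self.ensemble_drive_rate_hz < 0:
            raise ValueError("ensemble parameters must be non-negative")
        if any(c not in CLASSES for c in self.ensemble_classes):
            raise ValueError(f"ensemble_classes must be drawn from {CLASSES}")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        for key in ("class_mix", "ensemble_classes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Per-neuron class labels, ensemble labels (−1 = none), and, for paired
    sessions, the identity map to the companion session."""

    classes: tuple[str, ...]
    ensembles: tuple[int, ...]
    identity: dict[str, str] = field(default_factory=dict)

    def ids_of_class(self, ids: tuple[str, ...], cls: str) -> set[str]:
        return {i for i, c in zip(ids, self.classes) if c == cls}


def two_ensemble_config(**overrides) -> SimConfig:
    """Two latent ensembles driving otherwise behavior-irrelevant neurons;
    the preset used for ensemble-detection recovery experiments."""
    base = dict(
        class_mix=(0.0, 0.0, 1.0),
        n_ensembles=2,
        ensemble_drive_rate_hz=0.5,
        participation_p=0.9,
        noise_sd=0.1,
    )
    base.update(overrides)
    return SimConfig(**base)


def hyperconnectivity_config(base: SimConfig | None = None, **overrides) -> SimConfig:
    """Preset emulating a hyperconnected network phenotype: shared drive is
    stronger and more reliable, so pairwise similarities and degree
    centrality rise relative to the default configuration."""
    cfg = base or SimConfig()
    merged = dict(
        participation_p=min(1.0, cfg.participation_p + 0.35),
        ensemble_drive_rate_hz=cfg.ensemble_drive_rate_hz * 2.0,
    )
    merged.update(overrides)
    return replace(cfg, **merged)


def irrelevant_only_config(**overrides) -> SimConfig:
    """Behavior-independent neurons only: constant event rate, no ensemble
    drive.  The null-model preset for classifier and network calibration."""
    base = dict(
        class_mix=(0.0, 0.0, 1.0),
        n_ensembles=0,
        ensemble_drive_rate_hz=0.0,
        rate_base_hz=0.5,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------


def simulate_bouts(cfg: SimConfig, rng: np.random.Generator) -> BoutList:
    """Alternating renewal bout process.

    Gaps are exponential(mean_gap_s); bouts exponential(mean_bout_s)
    truncated below at 0.5 s; the sequence is clipped to the session
    duration.  Long-run bout fraction ≈ mean_bout / (mean_bout + mean_gap).
    """
    duration = cfg.duration_s
    intervals: list[tuple[float, float]] = []
    t = 0.0
    while True:
        t += rng.exponential(cfg.mean_gap_s)
        if t >= duration:
            break
        bout = max(MIN_BOUT_S, rng.exponential(cfg.mean_bout_s))
        end = min(t + bout, duration)
        if end > t:
            intervals.append((t, end))
        t = end
        if t >= duration:
            break
    if not intervals:
        warnings.warn("session too short for a single bout; empty BoutList")
    return BoutList(intervals=tuple(intervals), session_duration_s=duration)


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    counts = np.floor(np.asarray(cfg.class_mix) * cfg.n_neurons).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = np.asarray(cfg.class_mix) * cfg.n_neurons - counts
    for i in np.argsort(-frac)[: cfg.n_neurons - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(3), counts)
    return labels[rng.permutation(cfg.n_neurons)]


def _event_trains(
    cfg: SimConfig,
    class_idx: np.ndarray,
    ensemble_idx: np.ndarray,
    in_bout: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    dt = 1.0 / cfg.frame_rate_hz
    n, nf = cfg.n_neurons, cfg.n_frames
    # per-frame event probability by class and bout state
    p = np.empty((n, nf))
    p_on = min(1.0, cfg.rate_on_hz * dt)
    p_off = min(1.0, cfg.rate_off_hz * dt)
    p_base = min(1.0, cfg.rate_base_hz * dt)
    p[class_idx == 0] = np.where(in_bout, p_on, p_off)
    p[class_idx == 1] = np.where(in_bout, p_off, p_on)
    p[class_idx == 2] = p_base
    events = (rng.random((n, nf)) < p).astype(float)
    # shared latent drive per ensemble; each drive event recruits members
    # independently with participation_p
    p_drive = min(1.0, cfg.ensemble_drive_rate_hz * dt)
    for e in range(cfg.n_ensembles):
        members = np.flatnonzero(ensemble_idx == e)
        drive = rng.random(nf) < p_drive
        if members.size == 0:
            continue
        fired = drive[None, :] & (
            rng.random((members.size, nf)) < cfg.participation_p
        )
        events[members] += fired
    return events


def simulate_session(
    cfg: SimConfig, rng: np.random.Generator | None = None, session_id: str = "sim"
) -> tuple[TraceMatrix, BoutList, GroundTruth]:
    """Generate one session: raw non-negative traces, bouts, ground truth."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    bouts = simulate_bouts(cfg, rng)
    class_idx = _assign_classes(cfg, rng)
    eligible = np.isin(
        class_idx, [CLASSES.index(c) for c in cfg.ensemble_classes]
    )
    ensemble_idx = np.full(cfg.n_neurons, -1)
    if cfg.n_ensembles > 0:
        ensemble_idx[eligible] = rng.integers(
            0, cfg.n_ensembles, size=int(eligible.sum())
        )
    mid = (np.arange(cfg.n_frames) + 0.5) / cfg.frame_rate_hz
    in_bout = np.zeros(cfg.n_frames, dtype=bool)
    for start, end in bouts.intervals:
        in_bout |= (mid >= start) & (mid < end)
    events = _event_trains(cfg, class_idx, ensemble_idx, in_bout, rng)
    dt = 1.0 / cfg.frame_rate_hz
    kern_t = np.arange(0, 8 * cfg.kernel_tau_s, dt)
    kernel = np.exp(-kern_t / cfg.kernel_tau_s)
    traces = fftconvolve(events, kernel[None, :], axes=1)[:, : cfg.n_frames]
    if cfg.noise_sd > 0:
        traces = traces + rng.normal(0.0, cfg.noise_sd, traces.shape)
    traces = np.maximum(traces, 0.0)
    ids = tuple(f"{session_id}_n{i:04d}" for i in range(cfg.n_neurons))
    tm = TraceMatrix(
        session_id=session_id,
        neuron_ids=ids,
        frame_rate_hz=cfg.frame_rate_hz,
        activity=traces,
        normalization="raw_nonneg",
    )
    gt = GroundTruth(
        classes=tuple(CLASSES[i] for i in class_idx),
        ensembles=tuple(int(e) for e in ensemble_idx),
    )
    return tm, bouts, gt


def simulate_paired_sessions(
    cfg: SimConfig, session_ids: tuple[str, str] = ("sess1", "sess2")
) -> tuple[
    tuple[TraceMatrix, BoutList, GroundTruth],
    tuple[TraceMatrix, BoutList, GroundTruth],
]:
    """Two sessions sharing a subset of neurons.

    Each session-1 neuron reappears in session 2 with probability
    ``cross_session_overlap_p``, keeping its class and ensemble label but
    with freshly drawn events and noise; dropped slots are replaced by new
    neurons.  The identity map (stored in both GroundTruth objects) covers
    exactly the retained neurons.
    """
    rng = np.random.default_rng(cfg.seed)
    tm1, bouts1, gt1 = simulate_session(cfg, rng, session_id=session_ids[0])
    retained = rng.random(cfg.n_neurons) < cfg.cross_session_overlap_p
    tm2, bouts2, gt2 = simulate_session(cfg, rng, session_id=session_ids[1])
    # overwrite session-2 ground truth for retained slots so identity is real
    classes2 = list(gt2.classes)
    ensembles2 = list(gt2.ensembles)
    pairs: dict[str, str] = {}
    for i in np.flatnonzero(retained):
        classes2[i] = gt1.classes[i]
        ensembles2[i] = gt1.ensembles[i]
        pairs[tm1.neuron_ids[i]] = tm2.neuron_ids[i]
    # retained neurons' traces must follow their session-1 class: regenerate
    # rows where the class changed
    changed = [
        i for i in np.flatnonzero(retained) if gt2.classes[i] != classes2[i]
    ]
    if changed:
        sub_cfg = cfg
        class_idx = np.array([CLASSES.index(c) for c in classes2])
        mid = (np.arange(cfg.n_frames) + 0.5) / cfg.frame_rate_hz
        in_bout = np.zeros(cfg.n_frames, dtype=bool)
        for start, end in bouts2.intervals:
            in_bout |= (mid >= start) & (mid < end)
        events = _event_trains(
            sub_cfg, class_idx, np.array(ensembles2), in_bout, rng
        )
        dt = 1.0 / cfg.frame_rate_hz
        kern_t = np.arange(0, 8 * cfg.kernel_tau_s, dt)
        kernel = np.exp(-kern_t / cfg.kernel_tau_s)
        traces = fftconvolve(events, kernel[None, :], axes=1)[:, : cfg.n_frames]
        if cfg.noise_sd > 0:
            traces = traces + rng.normal(0.0, cfg.noise_sd, traces.shape)
        traces = np.maximum(traces, 0.0)
        act2 = tm2.activity.copy()
        act2[changed] = traces[changed]
        tm2 = replace(tm2, activity=act2)
    gt1 = GroundTruth(classes=gt1.classes, ensembles=gt1.ensembles, identity=pairs)
    gt2 = GroundTruth(
        classes=tuple(classes2),
        ensembles=tuple(ensembles2),
        identity={v: k for k, v in pairs.items()},
    )
    return (tm1, bouts1, gt1), (tm2, bouts2, gt2)
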