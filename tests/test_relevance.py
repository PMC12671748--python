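import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensembla.relevance import (
    classify_neurons,
    cosine_similarity,
    mean_bout_activity,
    relevance_ratios,
    session_overlap_table,
    shuffled_null,
)
from ensembla.simulate import SimConfig, simulate_paired_sessions, simulate_session
from ensembla.traces import (
    BehaviorVector,
    BoutList,
    DataError,
    IdentityMap,
    TraceMatrix,
    make_behavior_vector,
    zscore_traces,
)


def _behavior(n, bout_slices):
    v = np.zeros(n, dtype=np.int8)
    for a, b in bout_slices:
        v[a:b] = 1
    return BehaviorVector(values=v, frame_rate_hz=10.0)


def brute_force_shift_cosines(trace, b):
    """Independent oracle: cosine at every circular shift via explicit roll."""
    bv = b.values.astype(float)
    return np.array(
        [cosine_similarity(np.roll(trace, k), bv) for k in range(len(trace))]
    )


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        a = rng.random(50)
        assert cosine_similarity(a, a) == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        assert cosine_similarity([1, 0, 1, 0], [0, 1, 0, 1]) == 0.0

    def test_half_overlap(self):
        assert cosine_similarity([1, 0, 1, 0], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_zero_norm_rejected(self):
        with pytest.raises(DataError):
            cosine_similarity([0, 0, 0], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_nonneg_inputs_bounded_01(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random(20) + 1e-9, r.random(20) + 1e-9
        assert 0.0 <= cosine_similarity(a, b) <= 1.0


class TestShuffledNull:
    def test_fft_shift_cosines_match_brute_force(self, rng):
        """The FFT cross-correlation path equals explicit rolling on a
        100-frame toy, at every one of the 100 shifts."""
        from ensembla.relevance import _all_shift_cosines

        trace = rng.random(100) * 3
        b = _behavior(100, [(10, 30), (60, 75)])
        fft_cos = _all_shift_cosines(trace, b.values.astype(float))
        oracle = brute_force_shift_cosines(trace, b)
        np.testing.assert_allclose(fft_cos, oracle, atol=1e-12)

    def test_trace_equal_to_behavior_beats_every_shift(self):
        # R = 1 strictly exceeds all 99 shifted similarities (generic bouts)
        b = _behavior(100, [(10, 30), (55, 70)])
        trace = b.values.astype(float) + 0.01  # positive norm everywhere
        oracle = brute_force_shift_cosines(trace, b)
        assert oracle[0] == max(oracle)
        assert (oracle[1:] < oracle[0]).all()
        res = shuffled_null(trace, b, n_perm=500, seed=0)
        assert res["raw"] > res["null_p95"]

    def test_constant_trace_rejected(self):
        b = _behavior(100, [(10, 30)])
        with pytest.raises(DataError, match="constant trace"):
            shuffled_null(np.ones(100), b, n_perm=100, seed=0)

    def test_constant_behavior_rejected(self, rng):
        b = BehaviorVector(values=np.zeros(100, dtype=np.int8), frame_rate_hz=10.0)
        with pytest.raises(DataError, match="behavior"):
            shuffled_null(rng.random(100), b, n_perm=100, seed=0)

    def test_deterministic_under_seed(self, rng):
        trace = rng.random(200)
        b = _behavior(200, [(20, 60)])
        r1 = shuffled_null(trace, b, n_perm=300, seed=42)
        r2 = shuffled_null(trace, b, n_perm=300, seed=42)
        assert r1["null_p05"] == r2["null_p05"]
        assert r1["null_p95"] == r2["null_p95"]

    def test_permutation_mode_runs(self, rng):
        trace = rng.random(200)
        b = _behavior(200, [(20, 60)])
        res = shuffled_null(trace, b, n_perm=200, seed=0, mode="permutation")
        assert res["null_p05"] <= res["null_p95"]


class TestClassify:
    def _session(self, seed=0, **kw):
        cfg = SimConfig(seed=seed, **kw)
        tm, bouts, gt = simulate_session(cfg)
        b = make_behavior_vector(bouts, cfg.frame_rate_hz, cfg.n_frames)
        return tm, b, gt

    def test_anti_behavior_trace_labeled_negative(self):
        b = _behavior(6000, [(i * 150, i * 150 + 30) for i in range(40)])
        anti = (1.0 - b.values).astype(float)
        tm = TraceMatrix("s", ("a",), 10.0, anti[None, :])
        calls = classify_neurons(tm, b, n_perm=1000, seed=0)
        assert calls[0].label == "negative"

    def test_positive_class_detected(self):
        tm, b, gt = self._session(seed=5, n_neurons=40, n_frames=6000)
        calls = classify_neurons(tm, b, n_perm=500, seed=5)
        pos = [c.label for c, g in zip(calls, gt.classes) if g == "positive"]
        assert pos and np.mean([l == "positive" for l in pos]) >= 0.9

    def test_constant_neuron_flagged_irrelevant(self):
        b = _behavior(100, [(10, 30)])
        act = np.vstack([np.ones(100), np.linspace(0, 1, 100)])
        tm = TraceMatrix("s", ("const", "ramp"), 10.0, act)
        calls = classify_neurons(tm, b, n_perm=100, seed=0)
        assert calls[0].label == "irrelevant" and np.isnan(calls[0].R)

    def test_scale_invariance(self, rng):
        # cosine similarity is scale-free: rescaled traces, same labels
        tm, b, _ = self._session(seed=9, n_neurons=15, n_frames=2000)
        scaled = TraceMatrix(
            "s2", tm.neuron_ids, 10.0, tm.activity * 37.5
        )
        c1 = classify_neurons(tm, b, n_perm=300, seed=1)
        c2 = classify_neurons(scaled, b, n_perm=300, seed=1)
        assert [c.label for c in c1] == [c.label for c in c2]
        np.testing.assert_allclose(
            [c.R for c in c1], [c.R for c in c2], atol=1e-12
        )

    def test_zscored_input_rejected(self, rng):
        tm, b, _ = self._session(seed=1, n_neurons=5, n_frames=500)
        with pytest.raises(DataError, match="raw"):
            classify_neurons(zscore_traces(tm), b)


class TestRatios:
    def test_counts_and_percentages(self):
        from ensembla.relevance import RelevanceCall

        calls = (
            [RelevanceCall(f"p{i}", 0.9, 0.1, 0.8, "positive") for i in range(2)]
            + [RelevanceCall("n0", 0.05, 0.1, 0.8, "negative")]
            + [RelevanceCall(f"i{i}", 0.5, 0.1, 0.8, "irrelevant") for i in range(7)]
        )
        s = relevance_ratios(calls, 10)
        assert s.counts == {"positive": 2, "negative": 1, "irrelevant": 7}
        assert s.ratios_pct == {"positive": 20.0, "negative": 10.0, "irrelevant": 70.0}

    def test_registered_denominator(self):
        from ensembla.relevance import RelevanceCall

        calls = [RelevanceCall(f"p{i}", 0.9, 0.1, 0.8, "positive") for i in range(28)]
        assert relevance_ratios(calls, 300).ratios_pct["positive"] == 9.3

    def test_zero_denominator_rejected(self):
        with pytest.raises(DataError):
            relevance_ratios([], 0)


class TestMeanBoutActivity:
    def test_zscored_full_bout_mean_zero(self, rng):
        tm = zscore_traces(
            TraceMatrix("s", ("a", "b"), 10.0, rng.random((2, 100)))
        )
        b = BehaviorVector(values=np.ones(100, dtype=np.int8), frame_rate_hz=10.0)
        res = mean_bout_activity(tm, b, ["a", "b"])
        np.testing.assert_allclose(res["per_neuron"].values, 0.0, atol=1e-9)

    def test_positive_class_above_irrelevant_noise_free(self):
        cfg = SimConfig(
            n_neurons=30, n_frames=6000, noise_sd=0.0, seed=6,
            n_ensembles=0, ensemble_drive_rate_hz=0.0,
        )
        tm, bouts, gt = simulate_session(cfg)
        b = make_behavior_vector(bouts, 10.0, 6000)
        z = zscore_traces(tm)
        pos = gt.ids_of_class(tm.neuron_ids, "positive")
        irr = gt.ids_of_class(tm.neuron_ids, "irrelevant")
        assert (
            mean_bout_activity(z, b, pos)["group_mean"]
            > mean_bout_activity(z, b, irr)["group_mean"]
        )

    def test_empty_bouts_rejected(self, rng):
        tm = zscore_traces(TraceMatrix("s", ("a",), 10.0, rng.random((1, 50))))
        b = BehaviorVector(values=np.zeros(50, dtype=np.int8), frame_rate_hz=10.0)
        with pytest.raises(DataError, match="bout"):
            mean_bout_activity(tm, b, ["a"])


class TestSessionOverlap:
    def _calls(self, labels):
        from ensembla.relevance import RelevanceCall

        return [
            RelevanceCall(nid, 0.5, 0.1, 0.8, lab) for nid, lab in labels.items()
        ]

    def test_shared_responsive_counts(self):
        calls = {
            "s1": self._calls(
                {"a": "positive", "b": "positive", "c": "negative", "d": "irrelevant"}
            ),
            "s2": self._calls(
                {"x": "irrelevant", "y": "positive", "z": "negative", "w": "positive"}
            ),
        }
        maps = {("s1", "s2"): IdentityMap({"a": "x", "b": "y", "c": "z", "d": "w"})}
        res = session_overlap_table(calls, maps)
        # responsive in both: b→y and c→z (a maps to irrelevant x; d irrelevant)
        assert res["shared_responsive"][("s1", "s2")] == 2
        assert len(res["table"]) == 8

    def test_no_overlap_zero_counts(self):
        calls = {
            "s1": self._calls({"a": "positive"}),
            "s2": self._calls({"x": "positive"}),
        }
        res = session_overlap_table(calls, {("s1", "s2"): IdentityMap({})})
        assert res["shared_responsive"][("s1", "s2")] == 0

    def test_inconsistent_map_rejected(self):
        calls = {
            "s1": self._calls({"a": "positive"}),
            "s2": self._calls({"x": "positive"}),
        }
        with pytest.raises(DataError):
            session_overlap_table(
                calls, {("s1", "s2"): IdentityMap({"ghost": "x"})}
            )

    def test_paired_identical_overlap_recovers_responsive_set(self):
        """With total overlap the dual-responsive set equals the per-session
        responsive intersection computed through the identity map."""
        cfg = SimConfig(
            n_neurons=20, n_frames=3000, cross_session_overlap_p=1.0, seed=13
        )
        (t1, b1, g1), (t2, b2, g2) = simulate_paired_sessions(cfg)
        bv1 = make_behavior_vector(b1, 10.0, 3000)
        bv2 = make_behavior_vector(b2, 10.0, 3000)
        c1 = classify_neurons(t1, bv1, n_perm=300, seed=0)
        c2 = classify_neurons(t2, bv2, n_perm=300, seed=0)
        res = session_overlap_table(
            {"s1": c1, "s2": c2}, {("s1", "s2"): IdentityMap(g1.identity)}
        )
        resp1 = {c.neuron_id for c in c1 if c.label != "irrelevant"}
        resp2 = {c.neuron_id for c in c2 if c.label != "irrelevant"}
        expected = sum(1 for a in resp1 if g1.identity[a] in resp2)
        assert res["shared_responsive"][("s1", "s2")] == expected
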