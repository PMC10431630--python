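import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphts.graph import GridSpec, NodePath, TSGraph, build_graph
from graphts.io import AnomalyReport, ReportEntry
from graphts.scoring import (
    ScoreProfile,
    detect_topk,
    evaluate_topk,
    scan_lengths,
    score_profile,
    smooth_scores,
    subsequence_score,
)

GRID = GridSpec(n_c=4, x_min=0, x_max=1, y_min=0, y_max=1)


def _random_build(seed, n=200, n_ids=16):
    ids = np.random.default_rng(seed).integers(0, n_ids, size=n)
    path = NodePath(ids)
    return build_graph(path, GRID), path


class TestSubsequenceScore:
    def test_known_edge_weights(self):
        # path 0,1,2,3 with manually set weights 4,6,9: mean = 19/3
        g = TSGraph(n_c=4, edges={(0, 1): 4, (1, 2): 6, (2, 3): 9},
                    node_cells={i: (0, i) for i in range(4)})
        path = NodePath(np.array([0, 1, 2, 3]))
        assert subsequence_score(g, path, 0, 3) == pytest.approx(19 / 3)

    def test_constant_self_loop_path(self):
        g, path = build_graph(NodePath(np.array([5] * 30)), GRID), NodePath(np.array([5] * 30))
        assert subsequence_score(g, path, 3, 10) == 29.0  # every edge weight N-1

    def test_out_of_range_start_rejected(self):
        g, path = _random_build(0)
        with pytest.raises(ValueError):
            subsequence_score(g, path, len(path) - 3, 3)


class TestScoreProfile:
    @pytest.mark.parametrize("seed,length", [(0, 3), (1, 10), (2, 50)])
    def test_matches_per_index_recomputation(self, seed, length):
        g, path = _random_build(seed)
        prof = score_profile(g, path, length)
        assert len(prof) == len(path) - length
        oracle = [subsequence_score(g, path, i, length) for i in range(len(prof))]
        np.testing.assert_allclose(prof.scores, oracle, atol=1e-12)

    def test_weight_scaling_scales_scores_linearly(self):
        g, path = _random_build(3)
        scaled = TSGraph(n_c=g.n_c, edges={e: 7 * w for e, w in g.edges.items()},
                         node_cells=g.node_cells)
        np.testing.assert_allclose(
            score_profile(scaled, path, 12).scores,
            7 * score_profile(g, path, 12).scores,
            rtol=1e-12,
        )

    def test_length_too_large_rejected(self):
        g, path = _random_build(4, n=20)
        with pytest.raises(ValueError):
            score_profile(g, path, 20)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        prof = ScoreProfile(np.full(50, 3.5), length=5)
        np.testing.assert_array_equal(smooth_scores(prof, 7).scores, 3.5)

    def test_interior_impulse_spreads_uniformly(self):
        s = np.zeros(21)
        s[10] = 1.0
        out = smooth_scores(ScoreProfile(s, length=3), 5).scores
        np.testing.assert_allclose(out[8:13], 0.2)
        assert out[7] == 0.0 and out[13] == 0.0

    @given(seed=st.integers(0, 2000), m=st.integers(1, 60), w=st.integers(1, 20))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_windowed_mean_oracle(self, seed, m, w):
        s = np.random.default_rng(seed).normal(size=m)
        out = smooth_scores(ScoreProfile(s, length=2), w).scores
        left, right = (w - 1) // 2, w // 2
        oracle = [s[max(0, i - left): i + right + 1].mean() for i in range(m)]
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        assert len(out) == m


class TestDetectTopK:
    def test_single_global_minimum_is_rank_one(self):
        s = np.full(300, 10.0)
        s[137] = 1.0
        rep = detect_topk(ScoreProfile(s, length=20), k=1)
        assert rep.entries[0].start == 137 and rep.entries[0].rank == 1

    def test_nearby_minimum_masked_by_exclusion_zone(self):
        s = np.full(200, 10.0)
        s[100], s[110] = 1.0, 1.5  # 10 apart, exclusion 110 masks the second
        rep = detect_topk(ScoreProfile(s, length=110), k=2)
        assert [e.start for e in rep.entries] == [100]
        assert rep.truncated

    def test_ties_break_toward_earlier_start(self):
        s = np.full(200, 5.0)
        s[150] = s[30] = 1.0
        rep = detect_topk(ScoreProfile(s, length=10), k=2)
        assert [e.start for e in rep.entries] == [30, 150]

    def test_full_list_when_k_omitted(self, rng):
        s = rng.uniform(1, 2, size=500)
        rep = detect_topk(ScoreProfile(s, length=25))
        rep.validate()
        starts = sorted(e.start for e in rep.entries)
        assert all(b - a > 25 for a, b in zip(starts, starts[1:]))
        scores = [e.score for e in rep.entries]
        assert scores == sorted(scores)


class TestScanLengths:
    def test_single_length_scan_equals_detect(self):
        g, path = _random_build(7, n=400)
        res = scan_lengths(g, path, 20, 20, step=5, k=2, smooth_window=9)
        prof = smooth_scores(score_profile(g, path, 20), 9)
        direct = detect_topk(prof, k=2)
        assert list(res.per_length) == [20]
        assert [(e.start, e.score) for e in res.per_length[20].entries] == [
            (e.start, e.score) for e in direct.entries
        ]

    @pytest.mark.parametrize("lo,hi,step,expected", [(10, 50, 10, 5), (10, 50, 41, 1), (7, 7, 1, 1)])
    def test_number_of_scanned_lengths(self, lo, hi, step, expected):
        g, path = _random_build(8, n=300)
        res = scan_lengths(g, path, lo, hi, step=step)
        assert len(res.per_length) == expected

    def test_merged_list_has_disjoint_intervals(self):
        g, path = _random_build(9, n=500)
        res = scan_lengths(g, path, 10, 60, step=10, k=3, smooth_window=5)
        res.merged.validate()
        ivals = sorted((e.start, e.start + e.length) for e in res.merged.entries)
        assert all(b0 <= a1 for (_, b0), (a1, _) in zip(ivals, ivals[1:]))


class TestEvaluateTopK:
    def _rep(self, starts, length=10):
        return AnomalyReport(
            entries=[ReportEntry(i + 1, s, length, float(i)) for i, s in enumerate(starts)]
        )

    def test_all_matched(self):
        truth = [(0, 10), (50, 60), (100, 110)]
        assert evaluate_topk(self._rep([5, 55, 105]), truth) == 1.0

    def test_none_matched(self):
        assert evaluate_topk(self._rep([200, 300]), [(0, 10)]) == 0.0

    def test_partial_match_with_one_to_one_claiming(self):
        truth = [(0, 15), (100, 115), (200, 215), (300, 315)]
        # two detections on the same true interval: only one can claim it
        rep = self._rep([5, 8, 105, 205])
        assert evaluate_topk(rep, truth) == 0.75
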