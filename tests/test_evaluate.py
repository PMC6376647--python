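import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from stackdetect.evaluate import (
    compute_scores,
    density_map,
    density_profile,
    match_detections,
    pooled_match,
)
from stackdetect.iostack import AnnotationSet, DetectionSet


def _det(points):
    pts = np.array(points).reshape(len(points), 2)
    return DetectionSet(points=pts, confidences=np.ones(len(points)))


def _gt(points, shape=(200, 200)):
    pts = np.array(points).reshape(len(points), 2)
    return AnnotationSet(points=pts, image_shape=shape)


class TestMatchDetections:
    def test_identical_sets_all_true_positives(self):
        m = match_detections(_det([(10, 10), (40, 40)]), _gt([(10, 10), (40, 40)]))
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_distance_exactly_twenty_is_not_a_match(self):
        m = match_detections(_det([(0, 0)]), _gt([(0, 20)]), max_dist=20)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_distance_just_below_twenty_matches(self):
        m = match_detections(_det([(0, 0)]), _gt([(0, 19)]), max_dist=20)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_closest_candidate_wins(self):
        m = match_detections(_det([(0, 0)]), _gt([(0, 5), (0, 10)]))
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)
        [(pi, gi, d)] = m.pairs
        assert (pi, gi) == (0, 0)
        assert d == pytest.approx(5.0)

    def test_each_point_used_at_most_once(self):
        # two detections compete for one gt: the nearer wins, the other is fp
        m = match_detections(_det([(0, 4), (0, 6)]), _gt([(0, 0)]))
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.pairs[0][0] == 0

    def test_empty_sets(self):
        m = match_detections(_det([]), _gt([]))
        assert (m.tp, m.fp, m.fn) == (0, 0, 0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.tuples(st.integers(0, 99), st.integers(0, 99)),
                 min_size=0, max_size=12, unique=True),
        st.lists(st.tuples(st.integers(0, 99), st.integers(0, 99)),
                 min_size=0, max_size=12, unique=True),
    )
    def test_count_identities_on_fuzzed_point_sets(self, pred_pts, gt_pts):
        m = match_detections(_det(pred_pts), _gt(gt_pts, shape=(100, 100)))
        assert m.tp + m.fp == len(pred_pts)
        assert m.tp + m.fn == len(gt_pts)
        assert m.tp == len(m.pairs)
        assert all(d < 20 for _, _, d in m.pairs)
        assert len({p for p, _, _ in m.pairs}) == len(m.pairs)
        assert len({g for _, g, _ in m.pairs}) == len(m.pairs)

    def test_greedy_vs_optimal_bipartite_documented_comparison(self, rng):
        """Greedy ascending-distance matching is compared against optimal
        bipartite assignment on small random instances.  The two usually
        agree on the number of matches; where they differ greedy is the
        documented behaviour, so only agreement *when cardinality matches*
        is asserted, plus greedy never exceeding the optimum."""
        agree = 0
        total = 0
        for _ in range(40):
            npred, ngt = rng.integers(1, 9, 2)
            pred = _det(rng.integers(0, 60, (npred, 2)))
            gt_pts = np.unique(rng.integers(0, 60, (ngt, 2)), axis=0)
            gt = _gt(gt_pts, shape=(60, 60))
            m = match_detections(pred, gt)
            # optimal cardinality matching within the d<20 structure
            d = np.sqrt(((pred.points[:, None, :] - gt.points[None, :, :]) ** 2).sum(-1))
            cost = np.where(d < 20, d, 1e6)
            ri, ci = linear_sum_assignment(cost)
            opt_tp = int((cost[ri, ci] < 20).sum())
            assert m.tp <= opt_tp
            total += 1
            agree += m.tp == opt_tp
        assert agree / total > 0.8  # overwhelmingly the same cardinality


class TestComputeScores:
    def test_printed_formula_example(self):
        s = compute_scores((3, 1, 2))
        assert s.precision == pytest.approx(0.75)
        assert s.recall == pytest.approx(0.6)
        assert s.f1 == pytest.approx(2 * 0.45 / 1.35)

    def test_all_empty_convention_is_perfect(self):
        s = compute_scores((0, 0, 0))
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_perfect_detection(self):
        s = compute_scores((5, 0, 0))
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_no_detections_with_gt_scores_zero(self):
        s = compute_scores((0, 0, 7))
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0)

    def test_f1_symmetric_in_fp_fn(self, rng):
        for _ in range(20):
            tp, fp, fn = (int(v) for v in rng.integers(0, 20, 3))
            assert compute_scores((tp, fp, fn)).f1 == pytest.approx(
                compute_scores((tp, fn, fp)).f1
            )

    def test_pooled_match_sums_counts(self):
        a = match_detections(_det([(0, 0)]), _gt([(0, 0)]))
        b = match_detections(_det([(0, 0), (50, 50)]), _gt([(90, 90)]))
        pooled = pooled_match([a, b])
        assert (pooled.tp, pooled.fp, pooled.fn) == (1, 2, 1)


class TestDensity:
    def test_density_integrates_to_cell_count(self):
        # pad >= 4 sigma beyond the cells so the kernels fit in frame
        gt = _gt([(100, 100), (110, 120)], shape=(200, 220))
        dmap = density_map(gt, sigma=20.0)
        assert dmap.sum() == pytest.approx(2.0, rel=0.01)

    def test_single_cell_sits_at_density_maximum_in_top_bin(self):
        gt = _gt([(64, 64)], shape=(128, 128))
        match = match_detections(_det([(64, 64)]), gt)
        profile = density_profile(gt, match, sigma=10.0, n_bins=5)
        assert np.unravel_index(profile.density_map.argmax(),
                                profile.density_map.shape) == (64, 64)
        assert profile.per_bin[-1]["n_cells"] == 1
        assert sum(b["n_cells"] for b in profile.per_bin[:-1]) == 0

    def test_bin_cell_counts_partition_ground_truth(self, rng):
        pts = np.unique(rng.integers(0, 120, (40, 2)), axis=0)
        gt = _gt(pts, shape=(120, 120))
        det = _det(pts[::2])
        profile = density_profile(gt, match_detections(det, gt), sigma=15.0)
        assert sum(b["n_cells"] for b in profile.per_bin) == len(gt)

    def test_dense_cluster_cells_fall_in_higher_bins_than_sparse(self):
        """Two clusters, one 5x more populated: closed-form Gaussian-sum
        density is higher at every dense-cluster cell."""
        sparse = [(40, 40), (40, 50), (50, 45)]
        dense = [(160 + 5 * i, 160 + 7 * j) for i in range(3) for j in range(5)]
        gt = _gt(sparse + dense, shape=(256, 256))
        match = match_detections(_det(sparse + dense), gt)
        profile = density_profile(gt, match, sigma=50.0, n_bins=5)
        dmap = profile.density_map
        edges = profile.bin_edges
        sparse_bins = [np.digitize(dmap[p], edges[1:-1]) for p in sparse]
        dense_bins = [np.digitize(dmap[p], edges[1:-1]) for p in dense]
        assert max(sparse_bins) < min(dense_bins)

    def test_invalid_bins_rejected(self):
        gt = _gt([(5, 5)], shape=(10, 10))
        match = match_detections(_det([(5, 5)]), gt)
        with pytest.raises(ValueError):
            density_profile(gt, match, n_bins=0)

    def test_per_bin_counts_sum_to_match_totals(self, rng):
        pts = np.unique(rng.integers(0, 120, (30, 2)), axis=0)
        gt = _gt(pts, shape=(120, 120))
        det = _det(np.vstack([pts[::3], [[5, 115]]]))  # misses + one stray
        match = match_detections(det, gt)
        profile = density_profile(gt, match, sigma=15.0)
        assert sum(b["tp"] for b in profile.per_bin) == match.tp
        assert sum(b["fn"] for b in profile.per_bin) == match.fn
        assert sum(b["fp"] for b in profile.per_bin) == match.fp
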