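import numpy as np
import pytest

from stackdetect.adapt import AdaptConfig, adapt_iteratively, autolabel, find_peaks
from stackdetect.iostack import PlaneTriplet
from stackdetect.model import Heatmap, ModelConfig, build_detector
from stackdetect.targets import make_target_mask
from stackdetect.train import AugmentationParams, TrainSchedule
from tests.conftest import random_annotations


def brute_force_peaks(values, threshold, min_distance):
    """Independent oracle: enumerate supra-threshold maximal plateaus with
    pure-python flood fill, keep plateau centroid-nearest pixels, then greedy
    suppression by descending value (ties: row, then col)."""
    h, w = values.shape
    seen = np.zeros((h, w), dtype=bool)
    candidates = []
    for y in range(h):
        for x in range(w):
            if seen[y, x]:
                continue
            v = values[y, x]
            # flood-fill the equal-value plateau containing (y, x)
            stack = [(y, x)]
            plateau = []
            seen[y, x] = True
            is_max = True
            while stack:
                cy, cx = stack.pop()
                plateau.append((cy, cx))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if not (0 <= ny < h and 0 <= nx < w) or (dy == dx == 0):
                            continue
                        if values[ny, nx] == v and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                        elif values[ny, nx] > v:
                            is_max = False
            if is_max and v >= threshold:
                my = sum(p[0] for p in plateau) / len(plateau)
                mx = sum(p[1] for p in plateau) / len(plateau)
                best = min(plateau, key=lambda p: ((p[0] - my) ** 2 + (p[1] - mx) ** 2,
                                                   p[0], p[1]))
                candidates.append((v, best))
    candidates.sort(key=lambda t: (-t[0], t[1][0], t[1][1]))
    kept = []
    for v, (y, x) in candidates:
        if all((y - ky) ** 2 + (x - kx) ** 2 >= min_distance**2 for ky, kx in kept):
            kept.append((y, x))
    return sorted(kept)


class TestFindPeaks:
    def test_all_zero_heatmap_has_no_peaks(self):
        assert len(find_peaks(np.zeros((16, 16)), 0.2, 5)) == 0

    def test_subthreshold_peak_excluded(self):
        heat = np.zeros((16, 16))
        heat[8, 8] = 0.15
        assert len(find_peaks(heat, 0.2, 5)) == 0

    def test_close_pair_keeps_only_stronger(self):
        heat = np.zeros((16, 16))
        heat[8, 8] = 0.9
        heat[8, 11] = 0.8  # distance 3 < min_distance 5
        det = find_peaks(heat, 0.2, 5)
        assert det.points.tolist() == [[8, 8]]
        assert det.confidences.tolist() == [0.9]

    def test_far_pair_both_kept(self):
        heat = np.zeros((16, 16))
        heat[3, 3] = 0.9
        heat[12, 12] = 0.8
        assert len(find_peaks(heat, 0.2, 5)) == 2

    def test_plateau_contributes_one_point(self):
        heat = np.zeros((16, 16))
        heat[6:9, 6:9] = 0.7  # 3x3 flat plateau
        det = find_peaks(heat, 0.2, 5)
        assert det.points.tolist() == [[7, 7]]

    def test_confidences_are_heatmap_values(self, rng):
        heat = np.zeros((16, 16))
        heat[2, 2] = 0.35
        heat[12, 4] = 0.6
        det = find_peaks(heat, 0.2, 5)
        by_point = {tuple(p): c for p, c in zip(det.points, det.confidences)}
        assert by_point[(2, 2)] == pytest.approx(0.35)
        assert by_point[(12, 4)] == pytest.approx(0.6)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle_on_random_heatmaps(self, trial):
        rng = np.random.default_rng(1000 + trial)
        shape = (int(rng.integers(4, 33)), int(rng.integers(4, 33)))
        # quantized values make plateaus common
        heat = rng.integers(0, 12, shape) / 12.0
        got = sorted(map(tuple, find_peaks(heat, 0.25, 4).points.tolist()))
        assert got == brute_force_peaks(heat, 0.25, 4)

    def test_min_distance_is_euclidean(self):
        heat = np.zeros((16, 16))
        heat[8, 8] = 0.9
        heat[11, 12] = 0.8  # distance 5 exactly: kept when min_distance = 5
        assert len(find_peaks(heat, 0.2, 5)) == 2
        heat[11, 12] = 0.0
        heat[11, 11] = 0.8  # distance sqrt(18) < 5: suppressed
        assert len(find_peaks(heat, 0.2, 5)) == 1


class _ConstantHeatmapNet:
    """Stub detector returning a fixed heatmap regardless of input."""

    def __init__(self, heat):
        self.heat = np.asarray(heat, dtype=np.float32)

    def predict_proba(self, x):
        return np.repeat(self.heat[None], x.shape[0], axis=0)


class TestAutolabel:
    def _triplet(self, shape=(32, 32)):
        return PlaneTriplet(np.zeros((3, *shape), dtype=np.float32), (1, 2, 3))

    def test_single_peak_yields_radius6_disk(self):
        heat = np.zeros((32, 32))
        heat[16, 16] = 0.9
        net = _ConstantHeatmapNet(heat)
        [(_, mask, ann)] = autolabel(net, [self._triplet()], AdaptConfig())
        assert int(mask.mask.sum()) == 113  # lattice points with r <= 6
        assert ann.provenance == "pseudo"
        assert len(ann) == 1

    def test_zero_peaks_still_yields_background_sample(self):
        net = _ConstantHeatmapNet(np.zeros((32, 32)))
        out = autolabel(net, [self._triplet()], AdaptConfig())
        assert len(out) == 1
        assert not out[0][1].mask.any()

    def test_well_separated_peaks_give_distinct_components(self):
        from scipy import ndimage

        heat = np.zeros((64, 64))
        pts = [(10, 10), (10, 40), (40, 10), (50, 50)]  # pairwise >= 2*6+2 apart
        for p in pts:
            heat[p] = 0.8
        net = _ConstantHeatmapNet(heat)
        [(_, mask, _)] = autolabel(net, [self._triplet((64, 64))], AdaptConfig())
        assert ndimage.label(mask.mask, structure=np.ones((3, 3)))[1] == len(pts)

    def test_pseudo_disks_are_plain_union_no_shrinking(self):
        heat = np.zeros((32, 32))
        heat[16, 10] = 0.9
        heat[16, 18] = 0.8  # 8 px apart: radius-6 disks overlap and merge
        net = _ConstantHeatmapNet(heat)
        [(_, mask, _)] = autolabel(net, [self._triplet()], AdaptConfig())
        union = np.zeros((32, 32), dtype=bool)
        yy, xx = np.mgrid[0:32, 0:32]
        for c in ((16, 10), (16, 18)):
            union |= (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= 36
        np.testing.assert_array_equal(mask.mask, union)


def _source_pool(rng, n=3, side=32):
    pool = []
    for _ in range(n):
        ann = random_annotations(rng, shape=(side, side), n=3, min_sep=10)
        mask = make_target_mask(ann, max_radius=3)
        img = rng.normal(0, 0.1, (3, side, side)).astype(np.float32)
        img[1:] += mask.mask[None] * 1.0
        pool.append((PlaneTriplet(img, (1, 2, 3)), mask))
    return pool


class TestAdaptIteratively:
    @pytest.fixture()
    def setup(self, rng):
        net = build_detector(ModelConfig(depth=2, base_filters=2), rng=0)
        pool = _source_pool(rng)
        targets = [PlaneTriplet(rng.normal(0, 0.1, (3, 32, 32)).astype(np.float32), (1, 2, 3))
                   for _ in range(5)]
        cfg = AdaptConfig(n_cycles=6, epochs_per_cycle=2, peak_min_distance=3, pseudo_radius=3)
        sched = TrainSchedule(total_epochs=60, patch_sizes=(16, 32))
        return net, pool, targets, cfg, sched

    def test_six_cycles_with_balanced_mixing(self, setup):
        net, pool, targets, cfg, sched = setup
        _, history = adapt_iteratively(net, pool, targets, cfg=cfg, schedule=sched,
                                       aug=AugmentationParams().identity(), rng=1)
        assert len(history) == 6
        for h in history:
            assert abs(h["n_source_patches"] - h["n_pseudo_patches"]) <= 1
        lrs = [h["lr"] for h in history]
        assert lrs == [0.1 * 0.5**c for c in range(6)]

    def test_reproducible_from_seed(self, rng, setup):
        net, pool, targets, cfg, sched = setup
        results = []
        for _ in range(2):
            net_i = build_detector(ModelConfig(depth=2, base_filters=2), rng=0)
            net_i, hist = adapt_iteratively(net_i, pool, targets, cfg=cfg, schedule=sched,
                                            aug=AugmentationParams(), rng=99)
            results.append((hist, net_i.params))
        assert results[0][0] == results[1][0]
        for k in results[0][1]:
            np.testing.assert_array_equal(results[0][1][k], results[1][1][k])

    def test_fewer_target_images_than_draw_falls_back(self, setup):
        net, pool, targets, cfg, sched = setup
        _, history = adapt_iteratively(net, pool, targets[:2], cfg=cfg, schedule=sched,
                                       aug=AugmentationParams().identity(), rng=1)
        assert len(history) == 6  # sampled with replacement, no crash

    def test_empty_inputs_rejected(self, setup):
        net, pool, targets, cfg, sched = setup
        with pytest.raises(ValueError):
            adapt_iteratively(net, [], targets, cfg=cfg, schedule=sched)
        with pytest.raises(ValueError):
            adapt_iteratively(net, pool, [], cfg=cfg, schedule=sched)

    def test_source_masks_never_overwritten(self, setup):
        net, pool, targets, cfg, sched = setup
        before = [m.mask.copy() for _, m in pool]
        adapt_iteratively(net, pool, targets, cfg=cfg, schedule=sched,
                          aug=AugmentationParams().identity(), rng=1)
        for (_, m), orig in zip(pool, before):
            np.testing.assert_array_equal(m.mask, orig)


class TestAdaptConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(peak_threshold=0.0),
        dict(peak_threshold=1.0),
        dict(pseudo_radius=0),
        dict(source_fraction=0.0),
        dict(source_fraction=1.0),
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AdaptConfig(**kwargs)
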