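"""Detection scoring: distance-matched precision/recall/F1 and density-stratified accuracy.

True negatives are meaningless in point detection, so accuracy is
summarized by F1 over a one-to-one matching between detections and
ground-truth points: a detection counts as a true positive when a
ground-truth cell lies strictly closer than ``max_dist`` pixels
(default 20) and, among multiple candidates, only the closest is
accepted.  The matching is realized as greedy assignment over all
candidate pairs in ascending distance order, which is deterministic and
symmetric between the two point sets.

Density stratification smooths the ground-truth points into a density
map with a normal kernel (sigma = 50 px), splits the map's value range
into five equal-width bins, and scores each bin separately — sparse and
crowded regions of a culture are scored apart, exposing the typical
recall loss in dense populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from stackdetect.iostack import AnnotationSet, DetectionSet

__all__ = [
    "MatchResult",
    "Scores",
    "DensityProfile",
    "match_detections",
    "compute_scores",
    "pooled_match",
    "density_profile",
    "density_map",
]


@dataclass
class MatchResult:
    """One-to-one assignment between a detection set and a ground-truth set."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]  # (detection idx, gt idx, distance)
    pred: DetectionSet | None = None
    gt: AnnotationSet | None = None

    @property
    def matched_pred(self) -> set[int]:
        return {p for p, _, _ in self.pairs}

    @property
    def matched_gt(self) -> set[int]:
        return {g for _, g, _ in self.pairs}


@dataclass
class Scores:
    precision: float
    recall: float
    f1: float


def match_detections(pred: DetectionSet, gt: AnnotationSet, max_dist: float = 20.0) -> MatchResult:
    """Match detections to ground truth by ascending distance, strictly below ``max_dist``.

    All candidate pairs with Euclidean distance ``d < max_dist`` are
    sorted by ``d`` (ties broken by detection then ground-truth index)
    and accepted greedily, each point used at most once — so every
    accepted detection is paired with the closest still-available
    ground-truth point.  A pair at exactly ``max_dist`` is NOT a match.
    """
    np_, ng = len(pred), len(gt)
    pairs: list[tuple[int, int, float]] = []
    if np_ and ng:
        d = cdist(pred.points.astype(float), gt.points.astype(float))
        pi, gi = np.nonzero(d < max_dist)
        dist = d[pi, gi]
        order = np.lexsort((gi, pi, dist))
        used_p = np.zeros(np_, dtype=bool)
        used_g = np.zeros(ng, dtype=bool)
        for k in order:
            p, g = pi[k], gi[k]
            if used_p[p] or used_g[g]:
                continue
            used_p[p] = used_g[g] = True
            pairs.append((int(p), int(g), float(dist[k])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=np_ - tp, fn=ng - tp, pairs=pairs, pred=pred, gt=gt)


def compute_scores(m: MatchResult | tuple[int, int, int]) -> Scores:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R).

    Zero-denominator conventions: with no detections, precision is 1 only
    if there is also no ground truth (perfect empty agreement), else 0;
    symmetrically for recall; F1 is 0 when P + R = 0 except in the
    all-empty case, where all three scores are 1.
    """
    tp, fp, fn = (m.tp, m.fp, m.fn) if isinstance(m, MatchResult) else m
    if tp == 0 and fp == 0 and fn == 0:
        return Scores(precision=1.0, recall=1.0, f1=1.0)
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else (1.0 if fp == 0 else 0.0)
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return Scores(precision=precision, recall=recall, f1=f1)


def pooled_match(results: list[MatchResult]) -> MatchResult:
    """Sum TP/FP/FN over per-image results (pairs are not concatenated)."""
    return MatchResult(
        tp=sum(r.tp for r in results),
        fp=sum(r.fp for r in results),
        fn=sum(r.fn for r in results),
        pairs=[],
    )


def density_map(gt: AnnotationSet, sigma: float = 50.0) -> np.ndarray:
    """Unnormalized Gaussian-sum KDE of the cell locations.

    Each cell contributes a unit-mass normal kernel, so the map sums
    (times unit pixel area) to the number of cells when the image extends
    well past them.
    """
    h, w = gt.image_shape
    counts = np.zeros((h, w), dtype=float)
    if len(gt):
        counts[gt.points[:, 0], gt.points[:, 1]] += 1.0
    return ndimage.gaussian_filter(counts, sigma=sigma, mode="constant", truncate=4.0)


@dataclass
class DensityProfile:
    """Per-density-bin detection scores.

    ``bin_edges`` are five (by default) equal-width intervals over the
    density map's [min, max]; bins generally contain unequal areas and
    unequal cell counts.  ``per_bin`` rows carry the bin's density range,
    its ground-truth cell count, TP/FP/FN, and scores.
    """

    density_map: np.ndarray
    bin_edges: np.ndarray
    per_bin: list[dict] = field(default_factory=list)


def _bin_of(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(values, edges[1:-1], right=False)
    return np.clip(idx, 0, len(edges) - 2)


def density_profile(
    gt: AnnotationSet,
    match: MatchResult,
    sigma: float = 50.0,
    n_bins: int = 5,
) -> DensityProfile:
    """Stratify one image's detection scores by local cell density.

    Every ground-truth cell is assigned to the bin of the density value
    at its own location (giving per-bin recall via its TP/FN status);
    every detection is assigned by the density at the detection location
    (giving per-bin precision via its TP/FP status).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if match.pred is None or match.gt is None:
        raise ValueError("match must carry its point sets (as returned by match_detections)")
    dmap = density_map(gt, sigma=sigma)
    lo, hi = float(dmap.min()), float(dmap.max())
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, n_bins + 1)
    gt_bins = (
        _bin_of(dmap[gt.points[:, 0], gt.points[:, 1]], edges)
        if len(gt)
        else np.empty(0, dtype=int)
    )
    det_pts = match.pred.points
    det_bins = (
        _bin_of(dmap[det_pts[:, 0], det_pts[:, 1]], edges)
        if len(det_pts)
        else np.empty(0, dtype=int)
    )
    matched_gt = match.matched_gt
    matched_pred = match.matched_pred
    per_bin = []
    for b in range(n_bins):
        gt_here = np.flatnonzero(gt_bins == b)
        det_here = np.flatnonzero(det_bins == b)
        tp_r = sum(1 for i in gt_here if i in matched_gt)
        fn = len(gt_here) - tp_r
        tp_p = sum(1 for i in det_here if i in matched_pred)
        fp = len(det_here) - tp_p
        n_gt = len(gt_here)
        precision = tp_p / (tp_p + fp) if (tp_p + fp) else float("nan")
        recall = tp_r / (tp_r + fn) if (tp_r + fn) else float("nan")
        f1 = (
            2 * precision * recall / (precision + recall)
            if (tp_p + fp) and (tp_r + fn) and (precision + recall) > 0
            else float("nan")
        )
        per_bin.append(
            dict(bin=b, density_lo=float(edges[b]), density_hi=float(edges[b + 1]),
                 n_cells=n_gt, tp=tp_r, fn=fn, fp=fp,
                 precision=precision, recall=recall, f1=f1)
        )
    return DensityProfile(density_map=dmap, bin_edges=edges, per_bin=per_bin)
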