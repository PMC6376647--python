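"""Iterative unsupervised domain adaptation via pseudo-labeling.

A detector trained on one annotated cell line typically keeps high
precision on an unseen cell line while losing recall.  Those confident
predictions are good enough to *generate* training data: peaks of the
predicted heatmap (low threshold 0.2, minimum separation 5 px) are
marked as cells and dilated into disk targets (radius 6 px).  Each
10-epoch cycle re-predicts four randomly drawn target-domain images with
the current weights, mixes the pseudo-labeled patches 50/50 with the
original annotated source patches — the annotated half keeps false
positives/negatives from amplifying over iterations — and trains on,
halving the learning rate and switching the patch size per cycle.  Six
cycles (60 epochs) in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from stackdetect.iostack import AnnotationSet, DetectionSet, PlaneTriplet
from stackdetect.model import Heatmap, UNet
from stackdetect.targets import TargetMask, _disk_offsets
from stackdetect.train import (
    AugmentationParams,
    SGDNesterov,
    TrainSchedule,
    bce_loss,
    run_epoch,
    sample_patches,
    split_train_val,
)

logger = logging.getLogger(__name__)

__all__ = ["AdaptConfig", "find_peaks", "autolabel", "adapt_iteratively"]


@dataclass
class AdaptConfig:
    n_cycles: int = 6
    epochs_per_cycle: int = 10
    peak_threshold: float = 0.2
    peak_min_distance: int = 5
    pseudo_radius: int = 6
    n_target_images_per_cycle: int = 4
    source_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.peak_threshold < 1.0:
            raise ValueError("peak_threshold must lie strictly in (0, 1)")
        if self.pseudo_radius < 1:
            raise ValueError("pseudo_radius must be >= 1")
        if not 0.0 < self.source_fraction < 1.0:
            raise ValueError("source_fraction must lie strictly in (0, 1)")


def find_peaks(heatmap: Heatmap | np.ndarray, threshold: float = 0.2,
               min_distance: int = 5) -> DetectionSet:
    """Supra-threshold local maxima with greedy Euclidean separation.

    A local maximum is an 8-neighbourhood maximal pixel; a flat plateau of
    equal-valued maximal pixels contributes a single point, the pixel
    nearest the plateau centroid.  Candidates with value >= ``threshold``
    are kept greedily by descending value (ties broken by row then
    column), suppressing any later candidate closer than ``min_distance``
    (Euclidean) to an accepted one.
    """
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    h, w = values.shape
    # Pixels equal to the max of their 3x3 neighbourhood (weak maxima).
    local = ndimage.maximum_filter(values, size=3, mode="nearest") == values
    cand = local & (values >= threshold)
    if not cand.any():
        return DetectionSet(points=np.empty((0, 2), dtype=np.int64),
                            confidences=np.empty(0))
    # A weak maximum only counts if its whole equal-value plateau (which may
    # extend past the weak-maximum mask) sees no strictly greater neighbour;
    # an accepted plateau contributes its centroid-nearest pixel once.
    points: list[tuple[int, int]] = []
    confs: list[float] = []
    visited = np.zeros((h, w), dtype=bool)
    neighbours = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for y0, x0 in zip(*np.nonzero(cand)):
        if visited[y0, x0]:
            continue
        v = values[y0, x0]
        stack = [(int(y0), int(x0))]
        visited[y0, x0] = True
        plateau: list[tuple[int, int]] = []
        is_max = True
        while stack:
            cy, cx = stack.pop()
            plateau.append((cy, cx))
            for dy, dx in neighbours:
                ny, nx = cy + dy, cx + dx
                if not (0 <= ny < h and 0 <= nx < w):
                    continue
                nv = values[ny, nx]
                if nv > v:
                    is_max = False
                elif nv == v and not visited[ny, nx]:
                    visited[ny, nx] = True
                    stack.append((ny, nx))
        if not is_max:
            continue
        ys = np.array([p[0] for p in plateau])
        xs = np.array([p[1] for p in plateau])
        cy, cx = ys.mean(), xs.mean()
        k = int(np.lexsort((xs, ys, (ys - cy) ** 2 + (xs - cx) ** 2))[0])
        points.append((int(ys[k]), int(xs[k])))
        confs.append(float(v))
    if not points:
        return DetectionSet(points=np.empty((0, 2), dtype=np.int64),
                            confidences=np.empty(0))
    pts = np.asarray(points, dtype=np.int64)
    confs = np.asarray(confs, dtype=float)
    order = np.lexsort((pts[:, 1], pts[:, 0], -confs))
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            d2 = float(np.sum((pts[i] - pts[j]) ** 2))
            if d2 < min_distance**2:
                ok = False
                break
        if ok:
            kept.append(i)
    kept_arr = np.asarray(kept, dtype=int)
    return DetectionSet(points=pts[kept_arr], confidences=np.clip(confs[kept_arr], 0.0, 1.0))


def _dilate_points(points: np.ndarray, shape: tuple[int, int], radius: int) -> np.ndarray:
    """Union of lattice disks (binary dilation of the point set)."""
    mask = np.zeros(shape, dtype=bool)
    oy, ox = _disk_offsets(radius)
    h, w = shape
    for r0, c0 in points:
        yy = r0 + oy
        xx = c0 + ox
        keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        mask[yy[keep], xx[keep]] = True
    return mask


def autolabel(
    detector: UNet,
    triplets: list[PlaneTriplet],
    cfg: AdaptConfig | None = None,
) -> list[tuple[PlaneTriplet, TargetMask, AnnotationSet]]:
    """Generate pseudo training targets from the detector's own predictions.

    For each triplet the heatmap is predicted, peaks are extracted, and
    the peak points are dilated with a radius-``pseudo_radius`` disk into
    a binary target mask (plain union — unlike manual targets, pseudo
    disks are not shrunk apart).  Images without any peak still yield an
    (all-background) sample.  Returns one ``(triplet, mask, annotations)``
    tuple per input, annotations flagged ``provenance='pseudo'``.
    """
    cfg = cfg or AdaptConfig()
    out = []
    for triplet in triplets:
        x = np.asarray(triplet.channels, dtype=np.float32)[None]
        heat = detector.predict_proba(x)[0]
        det = find_peaks(heat, cfg.peak_threshold, cfg.peak_min_distance)
        mask = _dilate_points(det.points, heat.shape, cfg.pseudo_radius)
        target = TargetMask(mask=mask, max_radius=cfg.pseudo_radius,
                            per_cell_radius=np.full(len(det), cfg.pseudo_radius))
        ann = AnnotationSet(points=det.points, image_shape=heat.shape, provenance="pseudo")
        out.append((triplet, target, ann))
    return out


def adapt_iteratively(
    detector: UNet,
    source_pool: list[tuple[PlaneTriplet, TargetMask]],
    target_images: list[PlaneTriplet],
    cfg: AdaptConfig | None = None,
    schedule: TrainSchedule | None = None,
    aug: AugmentationParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[UNet, list[dict]]:
    """Adapt a trained detector to an unannotated target domain.

    Per cycle: draw ``n_target_images_per_cycle`` target images, pseudo-
    label them with the *current* weights, crop pseudo patches and mix
    them 1:1 with freshly cropped annotated source patches (source masks
    are never overwritten), then train ``epochs_per_cycle`` epochs at a
    learning rate of ``schedule.lr0 * lr_decay**cycle`` and the cycle's
    patch size.  A quarter of the mixed pool is held out to track
    validation loss.  No target-domain annotation is ever consulted.

    Returns the adapted detector and a per-cycle history with
    ``pseudo_cell_count`` (cells auto-labeled that cycle).
    """
    if not source_pool:
        raise ValueError("source_pool must be non-empty")
    if not target_images:
        raise ValueError("target_images must be non-empty")
    cfg = cfg or AdaptConfig()
    schedule = schedule or TrainSchedule()
    aug = aug if aug is not None else AugmentationParams()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    opt = SGDNesterov(momentum=schedule.momentum)
    history: list[dict] = []
    for cycle in range(cfg.n_cycles):
        lr = schedule.lr0 * schedule.lr_decay**cycle
        patch_size = schedule.patch_size_for_cycle(cycle)
        n_draw = cfg.n_target_images_per_cycle
        if len(target_images) >= n_draw:
            idx = rng.choice(len(target_images), size=n_draw, replace=False)
        else:
            idx = rng.choice(len(target_images), size=n_draw, replace=True)
            logger.warning(
                "only %d target images for %d requested; sampling with replacement",
                len(target_images), n_draw,
            )
        labeled = autolabel(detector, [target_images[i] for i in idx], cfg)
        pseudo_cells = int(sum(len(ann) for _, _, ann in labeled))
        pseudo_items = [(t, m) for t, m, _ in labeled]
        source_patches = sample_patches(source_pool, patch_size, rng)
        # Match the annotated half: as many pseudo patches as source patches.
        n_pseudo = max(1, int(round(len(source_patches) * (1 - cfg.source_fraction)
                                    / cfg.source_fraction)))
        per_img = max(1, int(np.ceil(n_pseudo / len(pseudo_items))))
        pseudo_patches = sample_patches(pseudo_items, patch_size, rng,
                                        patches_per_image=per_img)[:n_pseudo]
        pool = source_patches + pseudo_patches
        tr_idx, val_idx = split_train_val(len(pool), schedule.val_fraction, rng)
        train_patches = [pool[i] for i in tr_idx]
        val_patches = [pool[i] for i in val_idx] or train_patches
        train_loss = float("nan")
        for _ in range(cfg.epochs_per_cycle):
            train_loss = run_epoch(detector, opt, train_patches, lr,
                                   schedule.batch_size, aug, rng)
        val_loss = float(np.mean([
            bce_loss(detector.forward(img[None]), msk[None, None])
            for img, msk in val_patches
        ]))
        history.append(
            dict(cycle=cycle, lr=lr, patch_size=patch_size,
                 n_source_patches=len(source_patches),
                 n_pseudo_patches=len(pseudo_patches),
                 pseudo_cell_count=pseudo_cells,
                 train_loss=train_loss, val_loss=val_loss)
        )
    return detector, history
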