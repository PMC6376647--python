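"""Supervised training of the heatmap detector.

The schedule follows a simple cyclic regime: pixel-mean binary
cross-entropy, SGD with Nesterov momentum 0.8, batch size 5, learning
rate 0.1 halved after every 10-epoch cycle, and a different training
patch size per cycle (the network is fully convolutional, so the input
size can change freely; cycling sizes varies how much image border each
sample carries).  Fresh random patches are cropped from the training
images at the start of every cycle, one quarter of the images is held
out for validation, and the returned weights are those of the epoch with
the lowest validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from stackdetect.iostack import PlaneTriplet
from stackdetect.model import UNet, sigmoid
from stackdetect.targets import TargetMask

__all__ = [
    "TrainSchedule",
    "AugmentationParams",
    "lr_at_epoch",
    "augment",
    "train_supervised",
    "bce_loss",
    "SGDNesterov",
]


@dataclass
class TrainSchedule:
    total_epochs: int = 60
    cycle_length: int = 10
    lr0: float = 0.1
    lr_decay: float = 0.5
    momentum: float = 0.8
    batch_size: int = 5
    val_fraction: float = 0.25
    patch_sizes: tuple[int, ...] = (256, 384, 192, 320, 256, 384)

    def __post_init__(self) -> None:
        if self.total_epochs % self.cycle_length:
            raise ValueError("total_epochs must be divisible by cycle_length")

    @property
    def n_cycles(self) -> int:
        return self.total_epochs // self.cycle_length

    def patch_size_for_cycle(self, cycle: int) -> int:
        return self.patch_sizes[cycle % len(self.patch_sizes)]


@dataclass
class AugmentationParams:
    """Random patch transformations applied once per epoch per patch.

    Geometric transforms (right-angle rotations, flips) are applied
    jointly to image and mask and are interpolation-free, so the mask
    stays exactly binary.  Translation is realized as crop-offset jitter
    during patch extraction (``max_translation`` px).  Photometric
    transforms — a uniform additive intensity shift and Gaussian noise —
    touch the image only, never the mask.
    """

    rotations: tuple[int, ...] = (0, 90, 180, 270)
    flip: bool = True
    max_translation: int = 10
    intensity_shift: float = 0.1
    noise_sigma: float = 0.02

    def identity(self) -> "AugmentationParams":
        return replace(self, rotations=(0,), flip=False, max_translation=0,
                       intensity_shift=0.0, noise_sigma=0.0)


def lr_at_epoch(schedule: TrainSchedule, epoch: int) -> float:
    """Learning rate for a 0-based epoch: lr0 * decay^(epoch // cycle_length)."""
    if not 0 <= epoch < schedule.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {schedule.total_epochs})")
    return schedule.lr0 * schedule.lr_decay ** (epoch // schedule.cycle_length)


def augment(image: np.ndarray, mask: np.ndarray, params: AugmentationParams,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Randomly transform one (3, H, W) image patch and its (H, W) mask."""
    if image.shape[-2:] != mask.shape:
        raise ValueError("image and mask spatial shapes differ")
    img = image
    msk = mask
    if len(params.rotations) > 1 or params.rotations[0] % 360:
        angle = int(rng.choice(params.rotations))
        k = (angle // 90) % 4
        if k:
            img = np.rot90(img, k=k, axes=(-2, -1))
            msk = np.rot90(msk, k=k, axes=(-2, -1))
    if params.flip and rng.random() < 0.5:
        img = img[..., ::-1]
        msk = msk[..., ::-1]
    img = np.ascontiguousarray(img)
    msk = np.ascontiguousarray(msk)
    if params.intensity_shift > 0:
        img = img + np.float32(rng.uniform(-params.intensity_shift, params.intensity_shift))
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape).astype(np.float32)
    return img.astype(np.float32, copy=False), msk


def bce_loss(logits: np.ndarray, targets: np.ndarray,
             want_grad: bool = False):
    """Numerically stable pixel-mean binary cross-entropy on logits.

    Returns the scalar loss, and with ``want_grad`` also d(loss)/d(logits).
    """
    t = targets.astype(np.float32)
    z = logits
    loss = float(np.mean(np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    if not want_grad:
        return loss
    grad = (sigmoid(z) - t) / z.size
    return loss, grad.astype(np.float32)


class SGDNesterov:
    """SGD with Nesterov momentum (Keras/PyTorch formulation)."""

    def __init__(self, momentum: float = 0.8):
        self.momentum = momentum
        self.velocity: dict[str, np.ndarray] = {}

    def step(self, net: UNet, grads: dict[str, np.ndarray], lr: float) -> None:
        mu = self.momentum
        for k, g in grads.items():
            v = self.velocity.get(k)
            if v is None:
                v = np.zeros_like(g)
            v = mu * v - lr * g
            self.velocity[k] = v
            net.params[k] += mu * v - lr * g


# ---------------------------------------------------------------- patches

def sample_patches(
    items: list[tuple[PlaneTriplet, TargetMask]],
    patch_size: int,
    rng: np.random.Generator,
    patches_per_image: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Crop random (image, mask) patches of ``patch_size`` from full images.

    By default enough patches per image to cover its area once.  Crop
    offsets are uniform over all valid positions, which subsumes
    translation jitter.
    """
    out = []
    for triplet, target in items:
        h, w = target.shape
        if patch_size > h or patch_size > w:
            raise ValueError(f"patch size {patch_size} exceeds image {h}x{w}")
        n = patches_per_image
        if n is None:
            n = max(1, int(round(h * w / patch_size**2)))
        for _ in range(n):
            r0 = int(rng.integers(0, h - patch_size + 1))
            c0 = int(rng.integers(0, w - patch_size + 1))
            img = triplet.channels[:, r0 : r0 + patch_size, c0 : c0 + patch_size]
            msk = target.mask[r0 : r0 + patch_size, c0 : c0 + patch_size]
            out.append((np.ascontiguousarray(img, dtype=np.float32), msk.copy()))
    return out


def run_epoch(
    net: UNet,
    opt: SGDNesterov,
    patches: list[tuple[np.ndarray, np.ndarray]],
    lr: float,
    batch_size: int,
    aug: AugmentationParams,
    rng: np.random.Generator,
) -> float:
    """One pass over the patch list with augmentation; returns mean batch loss."""
    order = rng.permutation(len(patches))
    losses = []
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        imgs, msks = [], []
        for i in idx:
            im, mk = augment(patches[i][0], patches[i][1], aug, rng)
            imgs.append(im)
            msks.append(mk)
        x = np.stack(imgs)
        y = np.stack(msks)[:, None]
        logits, caches = net.forward(x, want_cache=True)
        loss, dlogits = bce_loss(logits, y, want_grad=True)
        grads = net.backward(dlogits, caches)
        opt.step(net, grads, lr)
        losses.append(loss)
    return float(np.mean(losses)) if losses else float("nan")


def validation_loss(net: UNet, items: list[tuple[PlaneTriplet, TargetMask]]) -> float:
    """Full-image BCE averaged over the validation images."""
    losses = []
    for triplet, target in items:
        x = np.asarray(triplet.channels, dtype=np.float32)[None]
        logits = net.forward(x)
        losses.append(bce_loss(logits, target.mask[None, None]))
    return float(np.mean(losses))


def split_train_val(
    n: int, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/validation index split, stable under the same rng state."""
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 1 else 0
    return np.sort(order[n_val:]), np.sort(order[:n_val])


def train_supervised(
    detector: UNet,
    dataset: list[tuple[PlaneTriplet, TargetMask]],
    schedule: TrainSchedule | None = None,
    aug: AugmentationParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[UNet, list[dict]]:
    """Train on annotated (triplet, target-mask) images; return best weights.

    A quarter of the images (``schedule.val_fraction``) is held out; the
    remaining images supply fresh random patches at the start of each
    10-epoch cycle, at that cycle's patch size.  Weights are checkpointed
    whenever the full-image validation loss reaches a new minimum, and the
    checkpointed weights are restored before returning.

    Returns the detector (mutated in place) and a per-epoch history of
    dicts ``{epoch, lr, patch_size, train_loss, val_loss, checkpointed}``.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    schedule = schedule or TrainSchedule()
    aug = aug if aug is not None else AugmentationParams()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    train_idx, val_idx = split_train_val(len(dataset), schedule.val_fraction, rng)
    train_items = [dataset[i] for i in train_idx]
    val_items = [dataset[i] for i in val_idx] or train_items
    opt = SGDNesterov(momentum=schedule.momentum)
    history: list[dict] = []
    best_loss = np.inf
    best_params = detector.copy_params()
    for cycle in range(schedule.n_cycles):
        patch_size = schedule.patch_size_for_cycle(cycle)
        patches = sample_patches(train_items, patch_size, rng)
        for e in range(schedule.cycle_length):
            epoch = cycle * schedule.cycle_length + e
            lr = lr_at_epoch(schedule, epoch)
            train_loss = run_epoch(detector, opt, patches, lr, schedule.batch_size, aug, rng)
            val_loss = validation_loss(detector, val_items)
            checkpointed = val_loss < best_loss
            if checkpointed:
                best_loss = val_loss
                best_params = detector.copy_params()
            history.append(
                dict(epoch=epoch, lr=lr, patch_size=patch_size,
                     train_loss=train_loss, val_loss=val_loss, checkpointed=checkpointed)
            )
    detector.set_params(best_params)
    return detector, history
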