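"""Reduced U-Net detector: 3-channel focus triplet -> per-pixel cell confidence.

The detector is a fully convolutional encoder–decoder with skip
connections that regresses a full-resolution heatmap in [0, 1] from three
consecutive focal planes.  Compared to the canonical 4-level U-Net, one
encoder/decoder level pair is removed (depth 3 by default) — intermediate
activations of the full network already carry the detections, so the
smaller symmetric network reaches the same accuracy at a fraction of the
compute.

The network, its gradients and the optimizer live in plain numpy: each
layer is a forward function plus a hand-derived backward function, and the
composite gradient is verified against numerical differentiation in the
test suite.  Arrays are NCHW ``float32``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from stackdetect.iostack import PlaneTriplet

__all__ = ["ModelConfig", "Heatmap", "UNet", "build_detector", "predict_heatmap",
           "save_detector", "load_detector", "sigmoid"]

_CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    depth : number of 2x down-sampling levels (input sides must be
        divisible by ``2**depth``).
    base_filters : channel count at the first level; doubles per level.
    """

    depth: int = 3
    base_filters: int = 16
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")


@dataclass
class Heatmap:
    """Per-pixel cell-confidence image in [0, 1], same resolution as the input."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"heatmap must be 2-D, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------- layers

def _conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution via im2col + one BLAS matmul."""
    N, C, H, Wd = x.shape
    F = W.shape[0]
    xp = np.zeros((N, C, H + 2, Wd + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1] = x
    cols = np.empty((N, H, Wd, C, 9), dtype=x.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[..., k] = xp[:, :, dy : dy + H, dx : dx + Wd].transpose(0, 2, 3, 1)
            k += 1
    cols = cols.reshape(N * H * Wd, C * 9)
    Wm = W.reshape(F, C * 9)
    out = cols @ Wm.T
    out += b
    out = out.reshape(N, H, Wd, F).transpose(0, 3, 1, 2)
    return out, (cols, x.shape)


def _conv3_backward(dout: np.ndarray, W: np.ndarray, cache):
    cols, xshape = cache
    N, C, H, Wd = xshape
    F = W.shape[0]
    dmat = dout.transpose(0, 2, 3, 1).reshape(N * H * Wd, F)
    Wm = W.reshape(F, C * 9)
    dW = (dmat.T @ cols).reshape(W.shape)
    db = dmat.sum(axis=0)
    dcols = (dmat @ Wm).reshape(N, H, Wd, C, 9)
    dxp = np.zeros((N, C, H + 2, Wd + 2), dtype=dout.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            dxp[:, :, dy : dy + H, dx : dx + Wd] += dcols[..., k].transpose(0, 3, 1, 2)
            k += 1
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _conv1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    Wm = W[:, :, 0, 0]
    out = np.einsum("fc,nchw->nfhw", Wm, x, optimize=True) + b[None, :, None, None]
    return out, x


def _conv1_backward(dout: np.ndarray, W: np.ndarray, x: np.ndarray):
    Wm = W[:, :, 0, 0]
    dW = np.einsum("nfhw,nchw->fc", dout, x, optimize=True)[:, :, None, None]
    db = dout.sum(axis=(0, 2, 3))
    dx = np.einsum("fc,nfhw->nchw", Wm, dout, optimize=True)
    return dx, dW, db


def _relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, x > 0


def _relu_backward(dout: np.ndarray, mask: np.ndarray):
    return dout * mask


def _maxpool2_forward(x: np.ndarray):
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, H // 2, W // 2, 4
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _maxpool2_backward(dout: np.ndarray, cache):
    idx, xshape = cache
    N, C, H, W = xshape
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, H, W
    )


def _upsample2_forward(x: np.ndarray):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(dout: np.ndarray):
    N, C, H, W = dout.shape
    return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------- network

class UNet:
    """Symmetric encoder–decoder heatmap regressor.

    Encoder: ``depth`` levels of (conv3x3 + ReLU) x 2 followed by 2x2
    max-pooling, channels doubling per level; a two-conv bottleneck; a
    mirrored decoder with 2x nearest-neighbour up-sampling and
    channel-concatenating skips; a zero-initialized 1x1 convolution +
    sigmoid head (an untrained detector therefore outputs exactly 0.5
    everywhere).  All convolutions are same-padded, so the heatmap has the
    input's resolution and any input whose sides divide by ``2**depth``
    can be predicted without rebuilding — patch sizes may change freely
    between training cycles.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params: dict[str, np.ndarray] = {}
        f = config.base_filters
        c_in = config.in_channels
        for i in range(config.depth):
            c_out = f * (2**i)
            self._add_conv(f"enc{i}_1", c_in, c_out, rng)
            self._add_conv(f"enc{i}_2", c_out, c_out, rng)
            c_in = c_out
        c_out = f * (2**config.depth)
        self._add_conv("bott_1", c_in, c_out, rng)
        self._add_conv("bott_2", c_out, c_out, rng)
        c_in = c_out
        for i in reversed(range(config.depth)):
            c_skip = f * (2**i)
            self._add_conv(f"dec{i}_1", c_in + c_skip, c_skip, rng)
            self._add_conv(f"dec{i}_2", c_skip, c_skip, rng)
            c_in = c_skip
        # Head starts at zero so the initial heatmap is the uninformative 0.5.
        self.params["head_W"] = np.zeros((1, f, 1, 1), dtype=np.float32)
        self.params["head_b"] = np.zeros(1, dtype=np.float32)

    def _add_conv(self, name: str, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        fan_in = c_in * 9
        std = np.sqrt(2.0 / fan_in)
        self.params[f"{name}_W"] = rng.normal(0.0, std, (c_out, c_in, 3, 3)).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

    # -- shape handling -------------------------------------------------

    def _check_shape(self, x: np.ndarray) -> None:
        div = 2**self.config.depth
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected input (N, {self.config.in_channels}, H, W), got {x.shape}"
            )
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input sides {x.shape[2]}x{x.shape[3]} must be divisible by 2^depth = {div}"
            )

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward ---------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits for a batch; with ``want_cache`` also the backprop caches."""
        self._check_shape(x)
        p = self.params
        caches: dict = {}
        skips = []
        # float32 throughout, except float64 is honoured (for numerical checks)
        dtype = np.float64 if x.dtype == np.float64 else np.float32
        h = np.ascontiguousarray(x, dtype=dtype)
        for i in range(self.config.depth):
            for j in (1, 2):
                name = f"enc{i}_{j}"
                h, cc = _conv3_forward(h, p[f"{name}_W"], p[f"{name}_b"])
                h, cr = _relu_forward(h)
                caches[name] = (cc, cr)
            skips.append(h)
            h, cp = _maxpool2_forward(h)
            caches[f"pool{i}"] = cp
        for name in ("bott_1", "bott_2"):
            h, cc = _conv3_forward(h, p[f"{name}_W"], p[f"{name}_b"])
            h, cr = _relu_forward(h)
            caches[name] = (cc, cr)
        for i in reversed(range(self.config.depth)):
            h = _upsample2_forward(h)
            n_up = h.shape[1]
            h = np.concatenate([skips[i], h], axis=1)
            caches[f"cat{i}"] = (skips[i].shape[1], n_up)
            for j in (1, 2):
                name = f"dec{i}_{j}"
                h, cc = _conv3_forward(h, p[f"{name}_W"], p[f"{name}_b"])
                h, cr = _relu_forward(h)
                caches[name] = (cc, cr)
        logits, ch = _conv1_forward(h, p["head_W"], p["head_b"])
        caches["head"] = ch
        if want_cache:
            return logits, caches
        return logits

    def backward(self, dlogits: np.ndarray, caches: dict) -> dict[str, np.ndarray]:
        """Parameter gradients given d(loss)/d(logits) from a cached forward."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dh, grads["head_W"], grads["head_b"] = _conv1_backward(
            dlogits, p["head_W"], caches["head"]
        )
        for i in range(self.config.depth):
            for j in (2, 1):
                name = f"dec{i}_{j}"
                cc, cr = caches[name]
                dh = _relu_backward(dh, cr)
                dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3_backward(
                    dh, p[f"{name}_W"], cc
                )
            n_skip, n_up = caches[f"cat{i}"]
            dskip = dh[:, :n_skip]
            dh = _upsample2_backward(dh[:, n_skip:])
            caches[f"dskip{i}"] = dskip
        for name in ("bott_2", "bott_1"):
            cc, cr = caches[name]
            dh = _relu_backward(dh, cr)
            dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3_backward(dh, p[f"{name}_W"], cc)
        for i in reversed(range(self.config.depth)):
            dh = _maxpool2_backward(dh, caches[f"pool{i}"])
            dh = dh + caches[f"dskip{i}"]
            for j in (2, 1):
                name = f"enc{i}_{j}"
                cc, cr = caches[name]
                dh = _relu_backward(dh, cr)
                dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3_backward(
                    dh, p[f"{name}_W"], cc
                )
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid heatmaps, shape (N, H, W)."""
        return sigmoid(self.forward(x))[:, 0]

    def copy_params(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.params)

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = copy.deepcopy(params)


def build_detector(config: ModelConfig, rng: np.random.Generator | int | None = None) -> UNet:
    """Construct a detector with He-initialized convolutions (seedable)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return UNet(config, rng)


def predict_heatmap(detector: UNet, triplet: PlaneTriplet) -> Heatmap:
    """Run the detector on one (normalized) plane triplet."""
    x = np.asarray(triplet.channels, dtype=np.float32)[None]
    return Heatmap(values=detector.predict_proba(x)[0])


def save_detector(detector: UNet, path: str | Path) -> None:
    """Write a single-file, versioned weight checkpoint (.npz)."""
    meta = dict(
        format_version=_CHECKPOINT_VERSION,
        depth=detector.config.depth,
        base_filters=detector.config.base_filters,
        in_channels=detector.config.in_channels,
    )
    np.savez(Path(path), __meta__=np.array(list(meta.items()), dtype=object),
             **detector.params)


def load_detector(path: str | Path) -> UNet:
    with np.load(Path(path), allow_pickle=True) as data:
        meta = dict(data["__meta__"].tolist())
        if int(meta["format_version"]) != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        config = ModelConfig(depth=int(meta["depth"]), base_filters=int(meta["base_filters"]),
                             in_channels=int(meta["in_channels"]))
        net = UNet(config, np.random.default_rng(0))
        net.params = {k: data[k] for k in data.files if k != "__meta__"}
    return net
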