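"""A compact numpy convolutional network engine.

Implements exactly what the 2.5D segmenter needs: 3x3 same-padding
convolutions (im2col + matmul), ReLU, 2x2 max pooling, nearest-neighbor
upsampling, skip concatenation, class-weighted softmax cross-entropy and
Adam — assembled into a small U-Net-style encoder–decoder. Pure numpy keeps
training deterministic (bit-for-bit given the seed) and fast enough at desk
scale: a depth-2, 8-channel model trains in about a minute on one CPU.

Arrays are ``(N, C, H, W)`` float64 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class TrainingError(RuntimeError):
    """Loss became non-finite during optimization."""


# ---------------------------------------------------------------------------
# Primitive layers (functional, with explicit caches)
# ---------------------------------------------------------------------------


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for 3x3 same convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """W: (C_out, C_in, 3, 3), b: (C_out,). Returns (out, cache)."""
    n, c, h, w = x.shape
    co = W.shape[0]
    cols = _im2col3(x)
    out = cols @ W.reshape(co, c * 9).T + b
    out = out.reshape(n, h, w, co).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, W)


def conv3x3_backward(dout: np.ndarray, cache):
    cols, x_shape, W = cache
    n, c, h, w = x_shape
    co = W.shape[0]
    dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, co)
    dW = (dflat.T @ cols).reshape(co, c, 3, 3)
    db = dflat.sum(axis=0)
    # Gradient w.r.t. input = convolution of dout with the flipped, transposed
    # kernel; reuse the forward conv instead of a scatter (col2im).
    W_flip = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_in, C_out, 3, 3)
    dx, _ = conv3x3_forward(dout, W_flip, np.zeros(c))
    return dx, dW, db


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout, mask):
    return dout * mask


def maxpool2_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape)


def maxpool2_backward(dout, cache):
    arg, x_shape = cache
    n, c, h, w = x_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(n, c, h, w)


def upsample2_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray) -> np.ndarray:
    """(N, K, H, W) -> class probabilities along axis 1."""
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def weighted_ce_loss(logits: np.ndarray, target: np.ndarray, class_weights: np.ndarray):
    """Pixelwise cross-entropy with per-class weights.

    target: (N, H, W) integer labels; class_weights: (K,). Returns
    (scalar loss, dlogits).
    """
    p = softmax(logits)
    n, k, h, w = logits.shape
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
    wpix = class_weights[target]  # (N, H, W)
    norm = max(wpix.sum(), 1e-12)
    logp = np.log(np.maximum(p, 1e-12))
    loss = -(wpix * np.take_along_axis(logp, target[:, None], axis=1)[:, 0]).sum() / norm
    dlogits = (p - onehot) * wpix[:, None] / norm
    return float(loss), dlogits


# ---------------------------------------------------------------------------
# The U-Net-style model
# ---------------------------------------------------------------------------


@dataclass
class UNet2D:
    """Small encoder–decoder with skip connections for per-pixel 2-class
    semantic segmentation of 3-plane slab inputs.

    ``depth`` pooling levels; channel counts double per level from ``base``.
    One 3x3 conv + ReLU per block (adequate for the smooth, high-contrast
    normalized marker signal), a 1x1-equivalent final 3x3 conv to K classes.
    """

    in_channels: int = 3
    n_classes: int = 2
    depth: int = 2
    base: int = 8
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.params:
            rng = np.random.default_rng(self.seed)
            chans = [self.in_channels] + [self.base * 2**i for i in range(self.depth + 1)]
            p: dict[str, np.ndarray] = {}
            for i in range(self.depth + 1):  # encoder blocks + bottleneck
                p[f"enc{i}_W"] = _he(rng, chans[i + 1], chans[i])
                p[f"enc{i}_b"] = np.zeros(chans[i + 1])
            for i in range(self.depth - 1, -1, -1):  # decoder blocks
                cin = chans[i + 2] + chans[i + 1]  # upsampled + skip
                p[f"dec{i}_W"] = _he(rng, chans[i + 1], cin)
                p[f"dec{i}_b"] = np.zeros(chans[i + 1])
            p["out_W"] = _he(rng, self.n_classes, chans[1])
            p["out_b"] = np.zeros(self.n_classes)
            self.params = p

    # -- forward ----------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        caches = []
        skips = []
        h = x
        for i in range(self.depth):
            h, cc = conv3x3_forward(h, self.params[f"enc{i}_W"], self.params[f"enc{i}_b"])
            h, rm = relu_forward(h)
            skips.append(h)
            h, pc = maxpool2_forward(h)
            caches.append(("enc", cc, rm, pc))
        h, cc = conv3x3_forward(
            h, self.params[f"enc{self.depth}_W"], self.params[f"enc{self.depth}_b"]
        )
        h, rm = relu_forward(h)
        caches.append(("bottleneck", cc, rm))
        for i in range(self.depth - 1, -1, -1):
            up = upsample2_forward(h)
            cat = np.concatenate([up, skips[i]], axis=1)
            h, cc = conv3x3_forward(cat, self.params[f"dec{i}_W"], self.params[f"dec{i}_b"])
            h, rm = relu_forward(h)
            caches.append(("dec", i, cc, rm, up.shape[1]))
        logits, cc = conv3x3_forward(h, self.params["out_W"], self.params["out_b"])
        caches.append(("out", cc))
        return (logits, caches) if want_cache else logits

    # -- backward ---------------------------------------------------------
    def backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        it = len(caches) - 1
        tag = caches[it]
        assert tag[0] == "out"
        dh, grads["out_W"], grads["out_b"] = conv3x3_backward(dlogits, tag[1])
        it -= 1
        dskips: dict[int, np.ndarray] = {}
        while caches[it][0] == "dec":
            _, i, cc, rm, n_up = caches[it]
            dcat, grads[f"dec{i}_W"], grads[f"dec{i}_b"] = conv3x3_backward(
                relu_backward(dh, rm), cc
            )
            dh = upsample2_backward(dcat[:, :n_up])
            dskips[i] = dcat[:, n_up:]
            it -= 1
        _, cc, rm = caches[it]
        dh, grads[f"enc{self.depth}_W"], grads[f"enc{self.depth}_b"] = conv3x3_backward(
            relu_backward(dh, rm), cc
        )
        it -= 1
        for i in range(self.depth - 1, -1, -1):
            _, cc, rm, pc = caches[it]
            dpool = maxpool2_backward(dh, pc)
            dpool = dpool + dskips[i]
            dh, grads[f"enc{i}_W"], grads[f"enc{i}_b"] = conv3x3_backward(
                relu_backward(dpool, rm), cc
            )
            it -= 1
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(N, 3, H, W) -> (N, K, H, W) class probabilities. H and W are
        padded (reflect) to a multiple of 2**depth and cropped back."""
        m = 2**self.depth
        n, c, h, w = x.shape
        ph, pw = (-h) % m, (-w) % m
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect") if ph or pw else x
        return softmax(self.forward(xp))[:, :, :h, :w]

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.params.values()))


def _he(rng: np.random.Generator, c_out: int, c_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (c_in * 9)), size=(c_out, c_in, 3, 3))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


@dataclass
class Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_model(model: UNet2D, path, extra: Optional[dict] = None) -> None:
    """Serialize weights + architecture to an .npz checkpoint."""
    meta = dict(
        in_channels=model.in_channels,
        n_classes=model.n_classes,
        depth=model.depth,
        base=model.base,
        seed=model.seed,
    )
    if extra:
        meta.update({f"extra_{k}": v for k, v in extra.items()})
    np.savez(path, __meta__=np.array([repr(meta)]), **model.params)


def load_model(path) -> tuple[UNet2D, dict]:
    with np.load(path, allow_pickle=False) as npz:
        meta = eval(str(npz["__meta__"][0]), {"__builtins__": {}})  # noqa: S307 - own file
        params = {k: npz[k] for k in npz.files if k != "__meta__"}
    extra = {k[6:]: v for k, v in meta.items() if k.startswith("extra_")}
    model = UNet2D(
        in_channels=int(meta["in_channels"]),
        n_classes=int(meta["n_classes"]),
        depth=int(meta["depth"]),
        base=int(meta["base"]),
        seed=int(meta["seed"]),
        params=params,
    )
    return model, extra
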