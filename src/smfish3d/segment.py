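"""2.5D semantic segmentation of marked neurons.

Each Z-slice is classified per pixel (cell vs background) by a small
encoder–decoder network (see :mod:`smfish3d.nn`) fed the three-plane slab
input of :func:`smfish3d.preprocess.build_slab_input`: the slice itself plus
maximum-intensity projections of its neighbors within a physical half-width
above and below. Per-slice probability maps are stacked into a volume,
binarized, and 26-connected components become the 3D cell mask. Touching
cells may share one label — the mask outlines the whole contiguous cluster,
and individual neurons are counted afterwards from the nuclear channel
(Otsu threshold restricted to the cell mask).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import filters

from .core_io import ImageStack, LabelMask
from .nn import Adam, TrainingError, UNet2D, weighted_ce_loss
from .preprocess import NormalizationParams, build_slab_input, histogram_stretch


@dataclass
class SegModelSpec:
    """Architecture and training hyperparameters for the slab segmenter."""

    depth: int = 2
    base_channels: int = 8
    iterations: int = 250
    batch_size: int = 4
    crop_size: int = 64
    learning_rate: float = 2e-3
    loss: str = "weighted_ce"
    brightness_factors: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 2.0)
    seed: int = 0


@dataclass
class MaskGeometry:
    """Volume statistics of one labeled region."""

    label: int
    voxel_count: int
    volume_um3: float
    equivalent_diameter_um: float


@dataclass
class SegmenterModel:
    """A trained segmenter plus the preprocessing it was trained with."""

    net: UNet2D
    spec: SegModelSpec
    norm: NormalizationParams
    w_um: float
    channel: int | str = "marker"
    val_iou: Optional[float] = None
    degenerate: bool = False  # all-background training set

    def checksum(self) -> float:
        return self.net.checksum()


def save_segmenter(model: SegmenterModel, path) -> None:
    """Write a single-file .npz checkpoint (weights + preprocessing)."""
    from .nn import save_model

    extra = dict(
        norm_low=model.norm.low_percentile,
        norm_high=model.norm.high_percentile,
        norm_lo_out=model.norm.output_range[0],
        norm_hi_out=model.norm.output_range[1],
        w_um=model.w_um,
        channel=str(model.channel),
        val_iou=-1.0 if model.val_iou is None else model.val_iou,
        degenerate=int(model.degenerate),
        spec_iterations=model.spec.iterations,
        spec_seed=model.spec.seed,
    )
    save_model(model.net, path, extra=extra)


def load_segmenter(path) -> SegmenterModel:
    from .nn import load_model

    net, extra = load_model(path)
    norm = NormalizationParams(
        low_percentile=float(extra["norm_low"]),
        high_percentile=float(extra["norm_high"]),
        output_range=(float(extra["norm_lo_out"]), float(extra["norm_hi_out"])),
    )
    channel: int | str = extra["channel"]
    if isinstance(channel, str) and channel.isdigit():
        channel = int(channel)
    spec = SegModelSpec(
        depth=net.depth, base_channels=net.base,
        iterations=int(extra.get("spec_iterations", 0)),
        seed=int(extra.get("spec_seed", net.seed)),
    )
    val_iou = float(extra.get("val_iou", -1.0))
    return SegmenterModel(
        net=net, spec=spec, norm=norm, w_um=float(extra["w_um"]),
        channel=channel, val_iou=None if val_iou < 0 else val_iou,
        degenerate=bool(int(extra.get("degenerate", 0))),
    )


def _stack_to_slabs(
    stack: ImageStack, channel: int | str, norm: NormalizationParams, w_um: float
) -> np.ndarray:
    """Normalize the channel per-stack, then build (nz, 3, H, W) slab inputs."""
    idx = stack.channel_index(channel)
    normalized = histogram_stretch(stack.voxels[idx], norm)
    tmp = ImageStack(
        voxels=normalized[np.newaxis],
        channel_names=["_norm"],
        voxel_size_um=stack.voxel_size_um,
    )
    nz = normalized.shape[0]
    return np.stack([build_slab_input(tmp, 0, z, w_um).as_array() for z in range(nz)])


def foreground_iou(pred: np.ndarray, truth: np.ndarray) -> Optional[float]:
    """Intersection-over-union of the foreground; None if truth is empty."""
    p = pred > 0
    t = truth > 0
    union = (p | t).sum()
    if t.sum() == 0:
        return None
    return float((p & t).sum() / union)


def train_segmenter(
    training_set: list[tuple[ImageStack, LabelMask]],
    spec: Optional[SegModelSpec] = None,
    norm: Optional[NormalizationParams] = None,
    w_um: float = 0.4,
    channel: int | str = "marker",
    holdout: int = 1,
) -> SegmenterModel:
    """Train the slab segmenter on annotated stacks.

    Training samples random crops of normalized slab inputs, applies random
    brightness factors (masks untouched), and minimizes class-weighted
    pixelwise cross-entropy with Adam. Deterministic given ``spec.seed``.
    The last ``holdout`` stacks (if at least two are provided) are held out
    and the foreground IoU on them is stored on the returned model.
    """
    if not training_set:
        raise ValueError("training set is empty")
    spec = spec or SegModelSpec()
    norm = norm or NormalizationParams()

    n_hold = holdout if len(training_set) > holdout else 0
    train_pairs = training_set[: len(training_set) - n_hold] if n_hold else training_set
    val_pairs = training_set[len(training_set) - n_hold:] if n_hold else []

    slabs, targets = [], []
    for stack, mask in train_pairs:
        slabs.append(_stack_to_slabs(stack, channel, norm, w_um))
        targets.append((mask.labels > 0).astype(np.int64))
    all_fg = sum(int(t.sum()) for t in targets)
    all_px = sum(t.size for t in targets)
    if all_fg == 0:
        warnings.warn(
            "all training masks are background; returning a degenerate "
            "background-only model", stacklevel=2,
        )
    # inverse-class-frequency weights (foreground is rare)
    freq = np.array([max(all_px - all_fg, 1), max(all_fg, 1)], float) / all_px
    class_weights = 1.0 / freq
    class_weights /= class_weights.sum()

    rng = np.random.default_rng(spec.seed)
    net = UNet2D(in_channels=3, n_classes=2, depth=spec.depth, base=spec.base_channels,
                 seed=spec.seed)
    opt = Adam(lr=spec.learning_rate)
    cs = spec.crop_size
    factors = list(spec.brightness_factors)

    for it in range(spec.iterations):
        xb, yb = [], []
        for _ in range(spec.batch_size):
            s = rng.integers(len(slabs))
            nz, _, hh, ww = slabs[s].shape
            z = rng.integers(nz)
            y0 = rng.integers(max(hh - cs, 0) + 1)
            x0 = rng.integers(max(ww - cs, 0) + 1)
            img = slabs[s][z, :, y0 : y0 + cs, x0 : x0 + cs]
            f = factors[rng.integers(len(factors))]
            img = np.clip(img * f, *norm.output_range)
            if rng.random() < 0.5:  # planes 2/3 are Z-mirror images of each other
                img = img[[0, 2, 1]]
            xb.append(img)
            yb.append(targets[s][z, y0 : y0 + cs, x0 : x0 + cs])
        x = np.stack(xb)
        y = np.stack(yb)
        logits, caches = net.forward(x, want_cache=True)
        loss, dlogits = weighted_ce_loss(logits, y, class_weights)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at iteration {it}")
        grads = net.backward(dlogits, caches)
        opt.step(net.params, grads)

    model = SegmenterModel(
        net=net, spec=spec, norm=norm, w_um=w_um, channel=channel,
        degenerate=(all_fg == 0),
    )
    if val_pairs and all_fg > 0:
        ious = []
        for stack, mask in val_pairs:
            prob = predict_slices(model, stack, channel, norm, w_um)
            iou = foreground_iou(prob >= 0.5, mask.labels)
            if iou is not None:
                ious.append(iou)
        model.val_iou = float(np.mean(ious)) if ious else None
    return model


def predict_slices(
    model: SegmenterModel,
    stack: ImageStack,
    channel: Optional[int | str] = None,
    norm: Optional[NormalizationParams] = None,
    w_um: Optional[float] = None,
    batch: int = 8,
) -> np.ndarray:
    """Per-slice inference; returns the (nz, H, W) cell-probability volume.

    The network is evaluated on both orderings of the above/below MIP planes
    and averaged, so predictions are exactly symmetric under Z reversal of
    the stack (matching the symmetry of the slab construction itself).
    """
    channel = model.channel if channel is None else channel
    norm = norm or model.norm
    w_um = model.w_um if w_um is None else w_um
    if model.degenerate:
        return np.zeros(stack.shape_zyx, np.float64)
    slabs = _stack_to_slabs(stack, channel, norm, w_um)
    probs = []
    for i in range(0, len(slabs), batch):
        x = slabs[i : i + batch]
        p1 = model.net.predict_proba(x)[:, 1]
        p2 = model.net.predict_proba(x[:, [0, 2, 1]])[:, 1]
        probs.append(0.5 * (p1 + p2))
    return np.concatenate(probs, axis=0)


def probability_to_mask(
    prob: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    threshold: float = 0.5,
    min_voxels: Optional[int] = None,
    min_volume_um3: float = 1.0,
) -> LabelMask:
    """Binarize a probability volume and label 3D 26-connected components.

    Components smaller than ``min_voxels`` (default: the voxel equivalent of
    ``min_volume_um3``) are dropped; remaining components are relabeled
    1..n in discovery order. Touching cells end up sharing a label.
    """
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if min_voxels is None:
        min_voxels = max(1, int(round(min_volume_um3 / float(np.prod(voxel_size_um)))))
    binary = prob >= threshold
    lab, n = ndimage.label(binary, structure=np.ones((3, 3, 3), int))
    if n == 0:
        return LabelMask(lab.astype(np.int32), "cell", voxel_size_um)
    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return LabelMask(remap[lab], "cell", voxel_size_um)


def segment_nuclei(
    stack: ImageStack,
    dapi_channel: int | str,
    cell_mask: LabelMask,
    min_voxels: Optional[int] = None,
    min_volume_um3: float = 0.5,
) -> LabelMask:
    """Nucleus mask: Otsu threshold on the DAPI channel inside the cell mask.

    3D 26-connected components at least ``min_voxels`` large are kept and
    labeled 1..n; by construction the nucleus mask is contained in the cell
    mask.
    """
    try:
        dapi = stack.channel(dapi_channel)
    except (KeyError, IndexError):
        raise ValueError(f"stack has no DAPI channel {dapi_channel!r}") from None
    if dapi.shape != cell_mask.labels.shape:
        raise ValueError("DAPI channel and cell mask shapes differ")
    if min_voxels is None:
        min_voxels = max(
            1, int(round(min_volume_um3 / float(np.prod(cell_mask.voxel_size_um))))
        )
    inside = cell_mask.labels > 0
    empty = LabelMask(
        np.zeros_like(cell_mask.labels, np.int32), "nucleus", cell_mask.voxel_size_um
    )
    if not inside.any():
        return empty
    vals = dapi[inside]
    if np.ptp(vals) == 0:
        return empty
    thr = filters.threshold_otsu(vals)
    binary = inside & (dapi > thr)
    lab, n = ndimage.label(binary, structure=np.ones((3, 3, 3), int))
    if n == 0:
        return empty
    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return LabelMask(remap[lab], "nucleus", cell_mask.voxel_size_um)


def mask_geometry(mask: LabelMask) -> list[MaskGeometry]:
    """Volume and equivalent diameter d = (6V/pi)^(1/3) per label."""
    voxel_vol = float(np.prod(mask.voxel_size_um))
    counts = np.bincount(mask.labels.ravel())
    out = []
    for lab in range(1, len(counts)):
        if counts[lab] == 0:
            continue
        vol = counts[lab] * voxel_vol
        out.append(
            MaskGeometry(
                label=lab,
                voxel_count=int(counts[lab]),
                volume_um3=vol,
                equivalent_diameter_um=float((6 * vol / np.pi) ** (1 / 3)),
            )
        )
    return out
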