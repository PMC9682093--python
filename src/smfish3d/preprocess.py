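"""Image conditioning for segmentation.

Two operations prepare the marker channel for the CNN: percentile histogram
stretching, which rescales the (bimodal) intensity histogram so the 2%
dimmest and 2% brightest voxels become the output minimum and maximum, and
2.5D slab construction, which packages each Z-slice with maximum-intensity
projections of its neighbors within a physical half-width (default 0.4 µm)
above and below — giving a 2D network three-dimensional context. Brightness
augmentation multiplies training images by a set of factors while leaving
label masks untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ImageStack, LabelMask


@dataclass
class NormalizationParams:
    low_percentile: float = 2.0
    high_percentile: float = 98.0
    output_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 <= self.low_percentile < self.high_percentile <= 100:
            raise ValueError("need 0 <= low < high <= 100")
        if not self.output_range[0] < self.output_range[1]:
            raise ValueError("output_range must be increasing")


@dataclass
class SlabInput:
    """Three aligned planes for one Z-slice: itself plus MIPs of the slices
    within ``w_um`` above and below."""

    current: np.ndarray
    mip_above: np.ndarray
    mip_below: np.ndarray
    z: int
    w_um: float

    def __post_init__(self) -> None:
        if not (self.current.shape == self.mip_above.shape == self.mip_below.shape):
            raise ValueError("slab planes must share one (y, x) shape")

    def as_array(self) -> np.ndarray:
        """(3, y, x) array: current, above-MIP, below-MIP."""
        return np.stack([self.current, self.mip_above, self.mip_below])


def histogram_stretch(
    array: np.ndarray, params: NormalizationParams | None = None
) -> np.ndarray:
    """Percentile contrast stretch (monotone, clipping the tails).

    The low/high percentile values of the input become the output range's
    minimum/maximum; values outside are clipped. Percentiles use linear
    interpolation between order statistics. A constant input maps to the
    output minimum.
    """
    params = params or NormalizationParams()
    a = np.asarray(array, dtype=np.float64)
    if a.size == 0:
        raise ValueError("cannot stretch an empty array")
    q_lo, q_hi = np.percentile(a, [params.low_percentile, params.high_percentile])
    lo_out, hi_out = params.output_range
    if q_hi == q_lo:
        return np.full_like(a, lo_out)
    scaled = np.clip((a - q_lo) / (q_hi - q_lo), 0.0, 1.0)
    return scaled * (hi_out - lo_out) + lo_out


def build_slab_input(
    stack: ImageStack, channel: int | str, z: int, w_um: float
) -> SlabInput:
    """2.5D input for one Z-slice.

    The neighbor set above is slices ``z+1 .. z+k`` with ``k = floor(w/dz)``
    (distance from the current plane), below analogously; the MIP is the
    voxelwise maximum over the set. At the stack boundary an empty neighbor
    set degrades to a copy of the current slice.
    """
    if w_um < 0:
        raise ValueError("w_um must be >= 0")
    vol = stack.channel(channel)
    nz = vol.shape[0]
    if not 0 <= z < nz:
        raise IndexError(f"z={z} out of range [0, {nz})")
    dz = stack.voxel_size_um[0]
    k = int(np.floor(w_um / dz))
    above = vol[z + 1 : min(nz, z + k + 1)]
    below = vol[max(0, z - k) : z]
    cur = vol[z]
    return SlabInput(
        current=cur.copy(),
        mip_above=above.max(axis=0) if above.shape[0] else cur.copy(),
        mip_below=below.max(axis=0) if below.shape[0] else cur.copy(),
        z=z,
        w_um=w_um,
    )


def augment_brightness(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    factors: list[float] = (0.5, 0.75, 1.25, 2.0),
    valid_range: tuple[float, float] = (0.0, 1.0),
    include_originals: bool = False,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Brightness-scale training images; masks are never altered.

    Each (image, mask) pair yields one pair per factor with the image
    multiplied and clipped to ``valid_range``; with ``include_originals`` the
    unscaled pairs are kept as well.
    """
    factors = list(factors)
    if any(f <= 0 for f in factors):
        raise ValueError("brightness factors must be positive")
    out: list[tuple[np.ndarray, np.ndarray]] = []
    if include_originals:
        out.extend((img.copy(), mask) for img, mask in pairs)
    for img, mask in pairs:
        for f in factors:
            out.append((np.clip(img * f, *valid_range), mask))
    return out
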