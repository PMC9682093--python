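"""Quality-control battery for detected spots and segmentation masks.

Because each mRNA is tiled by a similar number of fluorescent probes, spot
integrated intensities should form a single-mode histogram, should not
depend on Z position (sufficient working distance), and segmentation masks
should have consistent equivalent diameters. Each check is a pure function
of spot tables and masks; a summary table aggregates per-image rows and the
batch-level pass fraction of the Z screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core_io import LabelMask, SpotTable
from .segment import mask_geometry


@dataclass
class ZScreenResult:
    r: Optional[float]
    p: Optional[float]
    passed: Optional[bool]
    n: int


@dataclass
class QCReport:
    """All QC metrics for one image."""

    image: str
    n_spots: int
    median_intensity: Optional[float]
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    unimodal: Optional[bool]
    z_screen: ZScreenResult
    diameters_um: list[float] = field(default_factory=list)


def _count_modes(counts: np.ndarray, window: int = 3) -> int:
    """Prominent local maxima of the moving-average-smoothed histogram.

    The histogram is smoothed with a ``window``-bin moving average and peaks
    with prominence of at least 25% of the tallest smoothed bin are counted
    (small-count jitter creates shallow maxima that are not modes). The ends
    are padded below zero so a mode in the first or last bin still counts.
    This is a transparent heuristic, not a formal unimodality test.
    """
    if counts.sum() == 0:
        return 0
    kernel = np.ones(window) / window
    sm = np.convolve(counts.astype(float), kernel, mode="same")
    padded = np.concatenate([[-1.0], sm, [-1.0]])
    peaks, _ = signal.find_peaks(padded, prominence=0.25 * sm.max())
    return int(len(peaks))


def intensity_histogram(
    tables: list[SpotTable], bins: int = 30
) -> tuple[list[tuple[np.ndarray, np.ndarray]], tuple[np.ndarray, np.ndarray], list[Optional[bool]]]:
    """Per-image and merged spot-intensity histograms on shared bin edges.

    Edges span the pooled 1st–99th percentile range. Returns
    (per_image [(counts, edges)...], merged (counts, edges), unimodality
    flags). The flag counts local maxima of the 3-bin moving-average
    smoothed histogram; an empty table gets a null flag.
    """
    if not tables:
        raise ValueError("need at least one spot table")
    pooled = np.concatenate(
        [t.df["integrated_intensity"].to_numpy() for t in tables]
    ) if any(len(t) for t in tables) else np.array([])
    if pooled.size == 0:
        edges = np.linspace(0, 1, bins + 1)
    else:
        lo, hi = np.percentile(pooled, [1, 99])
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
    per_image = []
    flags: list[Optional[bool]] = []
    for t in tables:
        vals = t.df["integrated_intensity"].to_numpy()
        counts, _ = np.histogram(np.clip(vals, edges[0], edges[-1]), bins=edges)
        per_image.append((counts, edges))
        flags.append(_count_modes(counts) == 1 if len(vals) else None)
    merged_vals = np.clip(pooled, edges[0], edges[-1]) if pooled.size else pooled
    merged_counts, _ = np.histogram(merged_vals, bins=edges)
    return per_image, (merged_counts, edges), flags


def z_intensity_screen(table, alpha: float = 0.05) -> ZScreenResult:
    """Pearson correlation between spot intensity and Z position.

    Passing (no significant correlation, p >= alpha) is the expected behavior
    when working distance is sufficient. Fewer than 3 spots yields a null
    result with a warning; zero intensity variance counts as a pass (r = 0).
    ``table`` may be a :class:`SpotTable` or any frame with ``z_um`` and
    ``integrated_intensity`` columns.
    """
    df = table.df if isinstance(table, SpotTable) else table
    n = len(df)
    if n < 3:
        warnings.warn(f"z-screen needs >= 3 spots, got {n}; returning null result",
                      stacklevel=2)
        return ZScreenResult(r=None, p=None, passed=None, n=n)
    z = df["z_um"].to_numpy()
    inten = df["integrated_intensity"].to_numpy()
    if np.ptp(inten) == 0 or np.ptp(z) == 0:
        return ZScreenResult(r=0.0, p=1.0, passed=True, n=n)
    r, p = stats.pearsonr(inten, z)
    return ZScreenResult(r=float(r), p=float(p), passed=bool(p >= alpha), n=n)


def diameter_consistency(
    masks: list[LabelMask], fold_change: float = 2.0
) -> pd.DataFrame:
    """Equivalent-diameter summary per image with a fold-change outlier flag.

    The flag marks any diameter beyond ``fold_change`` times (or under 1 over
    that times) the batch median diameter. Note the flag is on diameter:
    a doubled *volume* changes the diameter only by 2^(1/3) and is not
    flagged at the default setting. Images with no labels are flagged.
    """
    all_d = []
    per_image = []
    for i, mask in enumerate(masks):
        d = [g.equivalent_diameter_um for g in mask_geometry(mask)]
        per_image.append(d)
        all_d.extend(d)
    batch_median = float(np.median(all_d)) if all_d else np.nan
    rows = []
    for i, d in enumerate(per_image):
        if d:
            outlier = any(
                dd > fold_change * batch_median or dd < batch_median / fold_change
                for dd in d
            )
            rows.append(
                dict(
                    image_index=i,
                    n_labels=len(d),
                    mean_diameter_um=float(np.mean(d)),
                    sem_diameter_um=float(np.std(d, ddof=1) / np.sqrt(len(d)))
                    if len(d) > 1 else 0.0,
                    flagged=bool(outlier),
                )
            )
        else:
            rows.append(
                dict(image_index=i, n_labels=0, mean_diameter_um=np.nan,
                     sem_diameter_um=np.nan, flagged=True)
            )
    return pd.DataFrame(rows)


def qc_report(
    image: str,
    table: SpotTable,
    mask: Optional[LabelMask] = None,
    alpha: float = 0.05,
    bins: int = 30,
) -> QCReport:
    """Assemble the full QC record for one image."""
    per_image, _, flags = intensity_histogram([table], bins=bins)
    counts, edges = per_image[0]
    inten = table.df["integrated_intensity"].to_numpy()
    return QCReport(
        image=image,
        n_spots=len(table),
        median_intensity=float(np.median(inten)) if len(inten) else None,
        hist_counts=counts,
        hist_edges=edges,
        unimodal=flags[0],
        z_screen=z_intensity_screen(table, alpha=alpha),
        diameters_um=[g.equivalent_diameter_um for g in mask_geometry(mask)]
        if mask is not None else [],
    )


def qc_summary(reports: list[QCReport]) -> pd.DataFrame:
    """One row per image plus batch aggregates in ``DataFrame.attrs``.

    ``attrs['z_screen_pass_fraction']`` is the fraction of images (with a
    defined screen) showing no significant intensity-vs-Z correlation.
    """
    rows = []
    for r in reports:
        rows.append(
            dict(
                image=r.image,
                n_spots=r.n_spots,
                median_intensity=r.median_intensity,
                unimodal=r.unimodal,
                z_r=r.z_screen.r,
                z_p=r.z_screen.p,
                z_pass=r.z_screen.passed,
                mean_diameter_um=float(np.mean(r.diameters_um)) if r.diameters_um else np.nan,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["image", "n_spots", "median_intensity", "unimodal", "z_r",
                 "z_p", "z_pass", "mean_diameter_um"],
    )
    defined = df["z_pass"].dropna() if len(df) else pd.Series(dtype=object)
    df.attrs["z_screen_pass_fraction"] = (
        float(defined.astype(bool).mean()) if len(defined) else np.nan
    )
    df.attrs["n_images"] = len(df)
    return df
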