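"""Per-cell transcript counting and between-condition statistics.

Spots are assigned to segmented regions by centroid containment at the voxel
grid: the fitted center (µm) is converted to its containing voxel (floor
convention) and takes the mask label there. Spots landing on background are
flagged extracellular and excluded from counts. Because touching neurons may
share one mask label, per-neuron values divide each label's total by the
number of neurons in the label (by default the number of nucleus components
inside it). Group comparisons use Welch's unpaired two-tailed t-test
(unequal variances, Welch–Satterthwaite degrees of freedom).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import LabelMask, SpotTable, containing_voxel

logger = logging.getLogger("smfish3d")


@dataclass
class CellQuant:
    """Counts for one mask label."""

    label: int
    count_cell: int
    count_nucleus: int
    count_cytoplasm: int
    volume_um3: float
    neurons_in_mask: int
    spots_per_neuron: float


@dataclass
class ComparisonResult:
    """Welch's t-test between two groups of per-cell (or per-neuron) counts."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p: float


def assign_spots(
    table: SpotTable,
    cell_mask: LabelMask,
    nucleus_mask: Optional[LabelMask] = None,
) -> pd.DataFrame:
    """Label each spot with its containing cell region (0 = extracellular).

    Returns the spot frame with ``label`` filled in and, when a nucleus mask
    is supplied, an ``in_nucleus`` boolean column.
    """
    if nucleus_mask is not None and nucleus_mask.labels.shape != cell_mask.labels.shape:
        raise ValueError("cell and nucleus masks have different shapes")
    df = table.df.copy()
    shape = cell_mask.labels.shape
    labels = np.zeros(len(df), np.int64)
    in_nuc = np.zeros(len(df), bool)
    for i, (x, y, z) in enumerate(zip(df["x_um"], df["y_um"], df["z_um"])):
        vz, vy, vx = containing_voxel((x, y, z), cell_mask.voxel_size_um)
        if not (0 <= vz < shape[0] and 0 <= vy < shape[1] and 0 <= vx < shape[2]):
            raise ValueError(f"spot {i} at ({x:g}, {y:g}, {z:g}) µm is outside the mask volume")
        labels[i] = cell_mask.labels[vz, vy, vx]
        if nucleus_mask is not None:
            in_nuc[i] = nucleus_mask.labels[vz, vy, vx] > 0
    df["label"] = labels
    if nucleus_mask is not None:
        df["in_nucleus"] = in_nuc
    return df


def neurons_per_label_from_nuclei(
    cell_mask: LabelMask, nucleus_mask: LabelMask
) -> dict[int, int]:
    """Count nucleus components inside each cell label (min 1 per label)."""
    out: dict[int, int] = {}
    for lab in cell_mask.label_ids:
        region = cell_mask.labels == lab
        nuc_ids = np.unique(nucleus_mask.labels[region])
        out[int(lab)] = max(1, int((nuc_ids > 0).sum()))
    return out


def per_cell_counts(
    assignments: pd.DataFrame,
    cell_mask: LabelMask,
    nucleus_mask: Optional[LabelMask] = None,
    neurons_per_label: Optional[dict[int, int]] = None,
) -> list[CellQuant]:
    """Aggregate assigned spots into per-label, per-compartment counts.

    ``neurons_per_label`` normalizes merged-mask totals to per-neuron values;
    when absent it is derived from the nucleus mask, or defaults to 1 with a
    logged warning (per-neuron numbers then equal per-mask numbers).
    """
    if neurons_per_label is None:
        if nucleus_mask is not None:
            neurons_per_label = neurons_per_label_from_nuclei(cell_mask, nucleus_mask)
        else:
            logger.warning("no nucleus mask: assuming 1 neuron per mask label")
            neurons_per_label = {}
    if any(v <= 0 for v in neurons_per_label.values()):
        raise ValueError("neurons_per_label values must be positive")

    voxel_vol = float(np.prod(cell_mask.voxel_size_um))
    counts = np.bincount(cell_mask.labels.ravel())
    has_nuc_col = "in_nucleus" in assignments.columns
    out: list[CellQuant] = []
    for lab in cell_mask.label_ids:
        lab = int(lab)
        in_cell = assignments[assignments["label"] == lab]
        total = len(in_cell)
        n_nuc = int(in_cell["in_nucleus"].sum()) if has_nuc_col else 0
        neurons = neurons_per_label.get(lab, 1)
        out.append(
            CellQuant(
                label=lab,
                count_cell=total,
                count_nucleus=n_nuc,
                count_cytoplasm=total - n_nuc,
                volume_um3=float(counts[lab] * voxel_vol) if lab < len(counts) else 0.0,
                neurons_in_mask=neurons,
                spots_per_neuron=total / neurons,
            )
        )
    return out


def quant_to_frame(quants: list[CellQuant], image: str = "", group: str = "") -> pd.DataFrame:
    df = pd.DataFrame([vars(q) for q in quants])
    if len(df):
        df.insert(0, "image", image)
        df.insert(1, "group", group)
    else:
        df = pd.DataFrame(
            columns=["image", "group", "label", "count_cell", "count_nucleus",
                     "count_cytoplasm", "volume_um3", "neurons_in_mask",
                     "spots_per_neuron"]
        )
    return df


def welch_t_test(
    group_a, group_b, label_a: str = "a", label_b: str = "b"
) -> ComparisonResult:
    """Unpaired two-tailed t-test assuming unequal variances.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with Welch–Satterthwaite
    degrees of freedom and a two-tailed p from Student's t distribution.
    Two identical zero-variance groups give t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        if ma == mb:
            t_stat, df, p = 0.0, float(na + nb - 2), 1.0
        else:
            t_stat, df, p = np.inf * np.sign(ma - mb), float(na + nb - 2), 0.0
    else:
        t_stat = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(2 * stats.t.sf(abs(t_stat), df))
    return ComparisonResult(
        group_a=label_a,
        group_b=label_b,
        mean_a=float(ma),
        mean_b=float(mb),
        sem_a=float(np.sqrt(va / na)),
        sem_b=float(np.sqrt(vb / nb)),
        t=float(t_stat),
        df=float(df),
        p=float(p),
    )


def holm_correction(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
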