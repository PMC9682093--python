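"""Run orchestration: a small dependency-aware, resumable executor.

The full workflow per image — segmentation and spot detection in parallel
branches, then centroid-in-mask assignment, quantification, QC and plots —
is tracked in a JSON run manifest. A stage is skipped when its recorded
parameter hash, input-file hashes and outputs are all unchanged, so
re-running with the same configuration recomputes nothing, while changing
only the detection threshold re-runs detection and everything downstream but
reuses the segmentation outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .core_io import (
    ImageStack,
    LabelMask,
    PipelineConfig,
    SpotTable,
    read_mask,
    read_spot_table,
    read_stack,
    write_mask,
    write_spot_table,
)
from .preprocess import NormalizationParams
from .qc import QCReport, qc_report, qc_summary
from .quantify import assign_spots, per_cell_counts, quant_to_frame, welch_t_test
from .segment import (
    SegmenterModel,
    load_segmenter,
    predict_slices,
    probability_to_mask,
    segment_nuclei,
)
from .spots import PSFParams, detect_spots, spots_to_table

logger = logging.getLogger("smfish3d")


@dataclass
class RunManifest:
    """Per-stage status and provenance of one pipeline run."""

    config_hash: str
    inputs: list[str]
    seed: int
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            dict(
                config_hash=self.config_hash,
                inputs=self.inputs,
                seed=self.seed,
                version=self.version,
                stages=self.stages,
            ),
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            config_hash=d["config_hash"],
            inputs=d["inputs"],
            seed=d["seed"],
            version=d.get("version", "?"),
            stages=d.get("stages", {}),
        )

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_json())


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _stage_fresh(manifest: RunManifest, name: str, params_hash: str,
                 input_files: list[Path]) -> bool:
    rec = manifest.stages.get(name)
    if not rec or rec.get("status") != "done":
        return False
    if rec.get("params_hash") != params_hash:
        return False
    if rec.get("input_hashes") != [_hash_file(p) for p in input_files]:
        return False
    return all(Path(o).exists() for o in rec.get("outputs", []))


def _record(manifest: RunManifest, name: str, params_hash: str,
            input_files: list[Path], outputs: list[Path], status: str = "done",
            error: str = "") -> None:
    manifest.stages[name] = dict(
        status=status,
        params_hash=params_hash,
        input_hashes=[_hash_file(p) for p in input_files if p.exists()],
        outputs=[str(o) for o in outputs],
        error=error,
    )


def run_pipeline(
    config: PipelineConfig,
    inputs: list[str | Path],
    out_dir: str | Path,
    model: SegmenterModel | str | Path,
    groups: Optional[dict[str, str]] = None,
) -> RunManifest:
    """Execute (or resume) the full analysis over a set of stack files.

    ``model`` is a trained segmenter or a checkpoint path; ``groups`` maps
    image names to condition labels (e.g. timepoints) for the final plots
    and the pairwise Welch tests. Failures in one image are recorded in the
    manifest and do not stop the others.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = [Path(p) for p in inputs]
    groups = groups or {}

    model_path: Optional[Path] = None
    if isinstance(model, (str, Path)):
        model_path = Path(model)
        seg_model = load_segmenter(model_path)
    else:
        seg_model = model

    cfg_hash = _hash_obj(json.loads(config.model_dump_json()))
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        manifest.config_hash = cfg_hash
        manifest.inputs = [str(p) for p in inputs]
        manifest.seed = config.seed
    else:
        manifest = RunManifest(
            config_hash=cfg_hash, inputs=[str(p) for p in inputs], seed=config.seed
        )

    seg_params = dict(
        low=config.low_percentile, high=config.high_percentile,
        w_um=config.slab_half_width_um, prob_threshold=config.prob_threshold,
        min_voxels_um3=config.min_voxels_um3,
        model=str(model_path) if model_path else f"mem:{seg_model.checksum():.9g}",
        marker=str(config.marker_channel), dapi=str(config.dapi_channel),
    )
    det_params = dict(
        threshold=config.detection_threshold, mode=config.threshold_mode,
        sigma_xy=config.psf.sigma_xy_nm, sigma_z=config.psf.sigma_z_nm,
        smfish=str(config.smfish_channel),
    )
    seg_hash = _hash_obj(seg_params)
    det_hash = _hash_obj(det_params)
    quant_hash = _hash_obj({"seg": seg_hash, "det": det_hash})
    psf = PSFParams(sigma_xy=config.psf.sigma_xy_nm, sigma_z=config.psf.sigma_z_nm)
    norm = NormalizationParams(config.low_percentile, config.high_percentile)

    quant_frames = []
    reports: list[QCReport] = []
    for src in inputs:
        name = src.stem.replace(".ome", "")
        img_dir = out_dir / name
        img_dir.mkdir(exist_ok=True)
        mask_cell_p = img_dir / "mask_cell.ome.tif"
        mask_nuc_p = img_dir / "mask_nucleus.ome.tif"
        spots_p = img_dir / "spots.csv"
        assigned_p = img_dir / "spots_in_cells.csv"
        percell_p = img_dir / "per_cell.csv"

        try:
            stack: Optional[ImageStack] = None

            def _stack() -> ImageStack:
                nonlocal stack
                if stack is None:
                    stack = read_stack(src, voxel_size_override=config.voxel_size_um)
                return stack

            # --- segmentation branch -----------------------------------
            stage = f"segment:{name}"
            if not _stage_fresh(manifest, stage, seg_hash, [src]):
                logger.info("running %s", stage)
                s = _stack()
                prob = predict_slices(seg_model, s, config.marker_channel, norm,
                                      config.slab_half_width_um)
                cell_mask = probability_to_mask(
                    prob, s.voxel_size_um, threshold=config.prob_threshold,
                    min_volume_um3=config.min_voxels_um3,
                )
                write_mask(cell_mask, mask_cell_p)
                outputs = [mask_cell_p]
                if config.dapi_channel is not None:
                    try:
                        nuc_mask = segment_nuclei(s, config.dapi_channel, cell_mask)
                        write_mask(nuc_mask, mask_nuc_p)
                        outputs.append(mask_nuc_p)
                    except ValueError as exc:
                        logger.warning("%s: skipping nuclei (%s)", name, exc)
                _record(manifest, stage, seg_hash, [src], outputs)
            else:
                logger.info("skipping %s (up to date)", stage)

            # --- detection branch --------------------------------------
            stage = f"detect:{name}"
            if not _stage_fresh(manifest, stage, det_hash, [src]):
                logger.info("running %s", stage)
                s = _stack()
                table = detect_spots(
                    s, config.smfish_channel, config.detection_threshold, psf,
                    threshold_mode=config.threshold_mode, source_image=name,
                )
                write_spot_table(table, spots_p)
                _record(manifest, stage, det_hash, [src], [spots_p])
            else:
                logger.info("skipping %s (up to date)", stage)

            # --- intersection + quantification -------------------------
            stage = f"quantify:{name}"
            stage_inputs = [mask_cell_p, spots_p]
            if not _stage_fresh(manifest, stage, quant_hash, stage_inputs):
                logger.info("running %s", stage)
                cell_mask = read_mask(mask_cell_p)
                nuc_mask = read_mask(mask_nuc_p) if mask_nuc_p.exists() else None
                table = read_spot_table(spots_p)
                assigned = assign_spots(table, cell_mask, nuc_mask)
                in_cells = assigned[assigned["label"] > 0]
                write_spot_table(
                    SpotTable(df=in_cells[table.df.columns], source_image=name,
                              params=table.params),
                    assigned_p,
                )
                quants = per_cell_counts(assigned, cell_mask, nuc_mask)
                qdf = quant_to_frame(quants, image=name, group=groups.get(name, name))
                qdf.to_csv(percell_p, index=False)
                _record(manifest, stage, quant_hash, stage_inputs,
                        [assigned_p, percell_p])
            else:
                logger.info("skipping %s (up to date)", stage)

            quant_frames.append(pd.read_csv(percell_p))
            in_table = read_spot_table(assigned_p)
            cell_mask = read_mask(mask_cell_p)
            reports.append(qc_report(name, in_table, cell_mask, alpha=config.alpha))
        except Exception:
            logger.exception("image %s failed", name)
            manifest.stages[f"failed:{name}"] = dict(
                status="failed", error=traceback.format_exc(), outputs=[]
            )
            continue

    # --- run-level outputs ---------------------------------------------
    quant_all = (
        pd.concat(quant_frames, ignore_index=True) if quant_frames
        else quant_to_frame([], "", "")
    )
    quant_all.to_csv(out_dir / "per_cell_all.csv", index=False)
    summary = qc_summary(reports)
    summary.to_csv(out_dir / "qc_summary.csv", index=False)
    (out_dir / "qc_summary.json").write_text(
        json.dumps(
            dict(
                z_screen_pass_fraction=summary.attrs.get("z_screen_pass_fraction"),
                n_images=summary.attrs.get("n_images"),
            ),
            indent=2,
        )
    )
    comparisons = _pairwise_comparisons(quant_all)
    comparisons.to_csv(out_dir / "comparisons.csv", index=False)
    make_plots(quant_all, reports, out_dir / "plots")
    _record(
        manifest, "aggregate", quant_hash, [],
        [out_dir / "per_cell_all.csv", out_dir / "qc_summary.csv",
         out_dir / "comparisons.csv"],
    )
    manifest.save(manifest_path)
    return manifest


def analyze_stack(
    stack: ImageStack,
    model: SegmenterModel,
    config: Optional[PipelineConfig] = None,
    name: str = "stack",
):
    """In-memory single-stack analysis (no files, no manifest).

    Runs segmentation, nucleus extraction, spot detection, assignment and
    per-cell counting; returns ``(cell_mask, nucleus_mask, spot_table,
    assigned_frame, cell_quants)``.
    """
    config = config or PipelineConfig()
    norm = NormalizationParams(config.low_percentile, config.high_percentile)
    psf = PSFParams(sigma_xy=config.psf.sigma_xy_nm, sigma_z=config.psf.sigma_z_nm)
    prob = predict_slices(model, stack, config.marker_channel, norm,
                          config.slab_half_width_um)
    cell_mask = probability_to_mask(
        prob, stack.voxel_size_um, threshold=config.prob_threshold,
        min_volume_um3=config.min_voxels_um3,
    )
    nucleus_mask = None
    if config.dapi_channel is not None:
        try:
            nucleus_mask = segment_nuclei(stack, config.dapi_channel, cell_mask)
        except ValueError as exc:
            logger.warning("%s: skipping nuclei (%s)", name, exc)
    table = detect_spots(
        stack, config.smfish_channel, config.detection_threshold, psf,
        threshold_mode=config.threshold_mode, source_image=name,
    )
    assigned = assign_spots(table, cell_mask, nucleus_mask)
    quants = per_cell_counts(assigned, cell_mask, nucleus_mask)
    return cell_mask, nucleus_mask, table, assigned, quants


def _pairwise_comparisons(quant: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if len(quant) and quant["group"].nunique() >= 2:
        names = sorted(quant["group"].unique())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = quant.loc[quant["group"] == names[i], "spots_per_neuron"]
                b = quant.loc[quant["group"] == names[j], "spots_per_neuron"]
                if len(a) >= 2 and len(b) >= 2:
                    res = welch_t_test(a, b, names[i], names[j])
                    rows.append(vars(res))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_a", "mean_b", "sem_a",
                       "sem_b", "t", "df", "p"]
    )


def make_plots(
    quant: pd.DataFrame,
    reports: list[QCReport],
    out_dir: str | Path,
    overlay_sources: Optional[list[tuple[ImageStack, LabelMask, SpotTable]]] = None,
) -> list[Path]:
    """Final and QC figures: per-group strip chart of spots/neuron with mean
    ± s.e.m. (annotated with the Welch p when exactly two groups), the
    intensity histograms, the intensity-vs-Z scatter, the diameter strip
    chart, and optional mask/spot overlay images."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if len(quant) and quant["group"].notna().any():
        fig, ax = plt.subplots(figsize=(4, 3.2))
        names = sorted(quant["group"].unique())
        rng = np.random.default_rng(0)
        for i, g in enumerate(names):
            vals = quant.loc[quant["group"] == g, "spots_per_neuron"].to_numpy()
            ax.scatter(i + rng.uniform(-0.12, 0.12, len(vals)), vals, s=14,
                       alpha=0.7, zorder=2)
            if len(vals):
                m = vals.mean()
                sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                ax.errorbar(i, m, yerr=sem, fmt="_", color="k", capsize=6,
                            markersize=18, zorder=3)
        ax.set_xticks(range(len(names)), names)
        ax.set_ylabel("smFISH spots / neuron")
        if len(names) == 2:
            a = quant.loc[quant["group"] == names[0], "spots_per_neuron"]
            b = quant.loc[quant["group"] == names[1], "spots_per_neuron"]
            if len(a) >= 2 and len(b) >= 2:
                res = welch_t_test(a, b, *names)
                ax.set_title(f"Welch p = {res.p:.3g}", fontsize=9)
        fig.tight_layout()
        p = out_dir / "spots_per_neuron.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    elif len(quant) == 0:
        logger.warning("empty quantification table: skipping group plot")

    if reports:
        fig, axes = plt.subplots(1, 3, figsize=(10, 3))
        for r in reports:
            centers = 0.5 * (r.hist_edges[:-1] + r.hist_edges[1:])
            axes[0].plot(centers, r.hist_counts, alpha=0.7, label=r.image)
        axes[0].set_xlabel("integrated intensity")
        axes[0].set_ylabel("spots")
        axes[0].set_title("spot intensity histograms", fontsize=9)
        for r in reports:
            if r.z_screen.r is not None:
                axes[1].scatter([r.image], [r.z_screen.p], s=18)
        axes[1].axhline(0.05, color="r", ls="--", lw=0.8)
        axes[1].set_ylabel("intensity-vs-Z p value")
        axes[1].tick_params(axis="x", rotation=45, labelsize=7)
        for i, r in enumerate(reports):
            axes[2].scatter([i] * len(r.diameters_um), r.diameters_um, s=18)
        axes[2].set_ylabel("equivalent diameter (µm)")
        axes[2].set_xlabel("image")
        fig.tight_layout()
        p = out_dir / "qc_panels.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    for stack, mask, table in overlay_sources or []:
        p = out_dir / f"overlay_{table.source_image or 'image'}.png"
        _overlay_figure(stack, mask, table, p)
        written.append(p)
    return written


def _overlay_figure(stack: ImageStack, mask: LabelMask, table: SpotTable,
                    path: Path) -> None:
    """Max-projection of the smFISH channel with mask outline and detected
    spot markers, for visual threshold tuning."""
    try:
        sm = stack.channel("smFISH")
    except (KeyError, IndexError):
        sm = stack.voxels[-1]
    mip = sm.max(axis=0)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(mip, cmap="gray")
    outline = (mask.labels > 0).max(axis=0)
    ax.contour(outline, levels=[0.5], colors="cyan", linewidths=0.8)
    dz, dy, dx = stack.voxel_size_um
    if len(table):
        ax.scatter(table.df["x_um"] / dx - 0.5, table.df["y_um"] / dy - 0.5,
                   s=10, facecolors="none", edgecolors="magenta", linewidths=0.6)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
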