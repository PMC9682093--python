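"""Shared fixtures: one trained segmenter and two analyzed scenarios.

Training and whole-stack analysis are the slow pieces, so they are built once
per session and reused by segmentation, quantification, pipeline and
end-to-end tests. The two scenarios mirror the expression peak (~80
transcripts per cell) and trough (~30 per cell) conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

import smfish3d as sf
from smfish3d.quantify import CellQuant
from smfish3d.segment import SegModelSpec, train_segmenter


@dataclass
class ScenarioCase:
    params: sf.ScenarioParams
    stack: sf.ImageStack
    gt: sf.GroundTruth


@dataclass
class AnalysisCase:
    scenario: ScenarioCase
    cell_mask: sf.LabelMask
    nucleus_mask: sf.LabelMask
    table: sf.SpotTable
    assigned: object
    quants: list[CellQuant]

    @property
    def mean_spots_per_neuron(self) -> float:
        total = sum(q.count_cell for q in self.quants)
        neurons = sum(q.neurons_in_mask for q in self.quants)
        return total / neurons


DEFAULT_CONFIG = sf.PipelineConfig(detection_threshold=3.0, threshold_mode="mad")


@pytest.fixture(scope="session")
def training_set():
    return sf.make_training_set(sf.ScenarioParams(seed=11), 10)


@pytest.fixture(scope="session")
def trained_model(training_set):
    """Segmenter trained at the ~10-annotated-stack scale."""
    return train_segmenter(training_set, SegModelSpec(iterations=250, seed=0))


@pytest.fixture(scope="session")
def zt4_scenario() -> ScenarioCase:
    params = sf.ScenarioParams(spots_per_cell=80, seed=21)
    stack, gt = sf.simulate_stack(params)
    return ScenarioCase(params, stack, gt)


@pytest.fixture(scope="session")
def zt16_scenario() -> ScenarioCase:
    params = sf.ScenarioParams(spots_per_cell=30, seed=22)
    stack, gt = sf.simulate_stack(params)
    return ScenarioCase(params, stack, gt)


def _analyze(model, case: ScenarioCase) -> AnalysisCase:
    cell_mask, nucleus_mask, table, assigned, quants = sf.analyze_stack(
        case.stack, model, DEFAULT_CONFIG
    )
    return AnalysisCase(case, cell_mask, nucleus_mask, table, assigned, quants)


@pytest.fixture(scope="session")
def zt4_analysis(trained_model, zt4_scenario) -> AnalysisCase:
    return _analyze(trained_model, zt4_scenario)


@pytest.fixture(scope="session")
def zt16_analysis(trained_model, zt16_scenario) -> AnalysisCase:
    return _analyze(trained_model, zt16_scenario)


@pytest.fixture(scope="session")
def isolated_spot_study():
    """50 well-separated spots at SNR 8 with the nominal 120/400 nm PSF."""
    stack, truth = sf.simulate_isolated_spots(50, snr=8.0, seed=7)
    return stack, truth


def brute_force_candidates(img: np.ndarray, threshold: float):
    """Independent O(n*27) reference for local-maximum candidate detection.

    A voxel qualifies if it is >= threshold and >= all 26 neighbors; within a
    connected equal-valued plateau of qualifying voxels only the
    lexicographically smallest index is kept.
    """
    nz, ny, nx = img.shape
    qual = set()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = img[z, y, x]
                if v < threshold:
                    continue
                ok = True
                for dz_ in (-1, 0, 1):
                    for dy_ in (-1, 0, 1):
                        for dx_ in (-1, 0, 1):
                            if dz_ == dy_ == dx_ == 0:
                                continue
                            zz, yy, xx = z + dz_, y + dy_, x + dx_
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                if img[zz, yy, xx] > v:
                                    ok = False
                if ok:
                    qual.add((z, y, x))
    # collapse equal-valued connected plateaus to their smallest index
    out = []
    seen: set = set()
    for idx in sorted(qual):
        if idx in seen:
            continue
        comp = [idx]
        frontier = [idx]
        seen.add(idx)
        while frontier:
            z, y, x = frontier.pop()
            for dz_ in (-1, 0, 1):
                for dy_ in (-1, 0, 1):
                    for dx_ in (-1, 0, 1):
                        nb = (z + dz_, y + dy_, x + dx_)
                        if nb in qual and nb not in seen and img[nb] == img[idx]:
                            seen.add(nb)
                            comp.append(nb)
                            frontier.append(nb)
        out.append(min(comp))
    return sorted(out)
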