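"""Quality-control battery: histograms, Z screen, diameter consistency."""

import numpy as np
import pandas as pd
import pytest

import smfish3d as sf
from smfish3d.core_io import SPOT_COLUMNS
from smfish3d.qc import (
    _count_modes,
    diameter_consistency,
    intensity_histogram,
    qc_report,
    qc_summary,
    z_intensity_screen,
)

VOXEL = (0.2, 0.05, 0.05)


def _table_from_intensities(intensities, z=None, seed=0):
    rng = np.random.default_rng(seed)
    n = len(intensities)
    df = pd.DataFrame({c: np.zeros(n) for c in SPOT_COLUMNS})
    df["integrated_intensity"] = np.asarray(intensities, float)
    df["z_um"] = z if z is not None else rng.uniform(0, 10, n)
    df["x_um"] = rng.uniform(0, 10, n)
    df["y_um"] = rng.uniform(0, 10, n)
    df["label"] = 1
    return sf.SpotTable(df=df)


class TestIntensityHistogram:
    def test_counts_conserve_spot_totals(self):
        rng = np.random.default_rng(1)
        tables = [_table_from_intensities(rng.lognormal(4, 0.1, n), seed=i)
                  for i, n in enumerate([50, 80, 10])]
        per_image, merged, _ = intensity_histogram(tables)
        for t, (counts, _) in zip(tables, per_image):
            assert counts.sum() == len(t)
        assert merged[0].sum() == 140

    def test_narrow_lognormal_is_unimodal(self):
        rng = np.random.default_rng(2)
        t = _table_from_intensities(rng.lognormal(4, 0.1, 400))
        _, _, flags = intensity_histogram([t])
        assert flags == [True]

    def test_bimodal_mixture_flagged(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(4, 0.05, 300)
        t = _table_from_intensities(np.concatenate([base, 2.5 * base]))
        _, _, flags = intensity_histogram([t])
        assert flags == [False]

    def test_single_spot_single_nonzero_bin(self):
        t = _table_from_intensities([100.0])
        per_image, _, _ = intensity_histogram([t])
        counts, _ = per_image[0]
        assert counts.sum() == 1
        assert (counts > 0).sum() == 1

    def test_empty_table_null_flag(self):
        _, _, flags = intensity_histogram([_table_from_intensities([])])
        assert flags == [None]

    def test_mode_counter_on_known_shapes(self):
        assert _count_modes(np.array([0, 2, 8, 2, 0, 0, 0])) == 1
        assert _count_modes(np.array([0, 8, 1, 0, 1, 9, 1])) == 2
        assert _count_modes(np.zeros(5, int)) == 0


class TestZIntensityScreen:
    def test_type_i_rate_on_attenuation_free_tables(self):
        """At alpha = 0.05 the pass rate over many clean images is ~95%."""
        tables = sf.simulate_spot_tables(200, n_spots=50, amplitude_cv=0.10,
                                         depth_attenuation_per_um=0.0, seed=5)
        passes = [z_intensity_screen(t, alpha=0.05).passed for t in tables]
        rate = np.mean(passes)
        assert rate >= 0.8
        # and within binomial noise of the nominal level
        assert rate >= 0.95 - 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_strong_attenuation_detected(self):
        # intensity halves across a 10 um stack: ln(2)/10 per um
        tables = sf.simulate_spot_tables(5, n_spots=50, amplitude_cv=0.10,
                                         depth_attenuation_per_um=np.log(2) / 10,
                                         seed=6)
        for t in tables:
            res = z_intensity_screen(t, alpha=0.05)
            assert res.passed is False
            assert res.p < 0.01
            assert res.r < 0

    def test_two_spots_null_result_with_warning(self):
        t = _table_from_intensities([10.0, 12.0])
        with pytest.warns(UserWarning, match=">= 3"):
            res = z_intensity_screen(t)
        assert res.passed is None

    def test_zero_variance_passes_by_convention(self):
        t = _table_from_intensities([7.0] * 10)
        res = z_intensity_screen(t)
        assert res.r == 0.0 and res.passed is True


class TestDiameterConsistency:
    def _uniform_masks(self, n=4, seed=7):
        rng = np.random.default_rng(seed)
        masks = []
        for _ in range(n):
            labels = np.zeros((20, 40, 40), np.int32)
            labels[4:16, 8:32, 8:32] = 1  # identical boxes
            masks.append(sf.LabelMask(labels, "cell", VOXEL))
        return masks

    def test_homogeneous_batch_not_flagged(self):
        df = diameter_consistency(self._uniform_masks())
        assert not df["flagged"].any()
        assert df["n_labels"].tolist() == [1, 1, 1, 1]

    def test_doubled_volume_is_not_a_diameter_outlier(self):
        """2x volume is only 2^(1/3) ~ 1.26x diameter: below the 2x flag."""
        masks = self._uniform_masks()
        labels = np.zeros((20, 40, 40), np.int32)
        labels[2:18, 4:36, 4:36] = 0
        labels[4:16, 8:32, 8:32] = 1
        big = masks[0].labels.copy()
        doubled = np.zeros((20, 40, 40), np.int32)
        doubled[4:16, 2:38, 8:32] = 1  # ~1.5x; pad with extra z to double
        doubled[2:4, 2:38, 8:32] = 1
        masks.append(sf.LabelMask(doubled, "cell", VOXEL))
        df = diameter_consistency(masks, fold_change=2.0)
        assert not df.iloc[-1]["flagged"]

    def test_extreme_outlier_flagged(self):
        masks = self._uniform_masks()
        tiny = np.zeros((20, 40, 40), np.int32)
        tiny[10, 20, 20:22] = 1
        masks.append(sf.LabelMask(tiny, "cell", VOXEL))
        df = diameter_consistency(masks, fold_change=2.0)
        assert bool(df.iloc[-1]["flagged"])

    def test_empty_mask_row_flagged(self):
        masks = self._uniform_masks(2)
        masks.append(sf.LabelMask(np.zeros((4, 4, 4), np.int32), "cell", VOXEL))
        df = diameter_consistency(masks)
        assert df.iloc[-1]["n_labels"] == 0
        assert bool(df.iloc[-1]["flagged"])


class TestQCSummary:
    def _clean_reports(self, n=10, seed=8):
        tables = sf.simulate_spot_tables(n, n_spots=60, seed=seed)
        return [
            qc_report(f"img{i}", sf.SpotTable(df=_full_frame(t)), None)
            for i, t in enumerate(tables)
        ]

    def test_clean_batch_pass_fraction(self):
        df = qc_summary(self._clean_reports())
        assert df.attrs["z_screen_pass_fraction"] >= 0.8
        assert len(df) == 10

    def test_injected_attenuated_image_fails_its_row(self):
        reports = self._clean_reports(9)
        bad = sf.simulate_spot_tables(1, n_spots=60, seed=9,
                                      depth_attenuation_per_um=np.log(2) / 10)[0]
        reports.append(qc_report("bad", sf.SpotTable(df=_full_frame(bad)), None))
        df = qc_summary(reports)
        assert df.loc[df["image"] == "bad", "z_pass"].item() is False
        passed = df["z_pass"].astype(bool)
        if passed[:9].all():
            assert df.attrs["z_screen_pass_fraction"] == pytest.approx(0.9)

    def test_empty_input_empty_table(self):
        df = qc_summary([])
        assert len(df) == 0

    def test_reports_are_pure_functions(self, zt4_analysis):
        r1 = qc_report("a", zt4_analysis.table, zt4_analysis.cell_mask)
        r2 = qc_report("a", zt4_analysis.table, zt4_analysis.cell_mask)
        assert r1.z_screen == r2.z_screen
        np.testing.assert_array_equal(r1.hist_counts, r2.hist_counts)
        assert r1.diameters_um == r2.diameters_um


def _full_frame(t: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame({c: np.zeros(len(t)) for c in SPOT_COLUMNS})
    for c in ("x_um", "y_um", "z_um", "integrated_intensity"):
        df[c] = t[c].to_numpy()
    df["label"] = 1
    return df
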