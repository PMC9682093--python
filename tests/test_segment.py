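"""Segmenter training/inference, mask assembly, nuclei, mask geometry."""

import numpy as np
import pytest

import smfish3d as sf
from smfish3d.segment import (
    SegModelSpec,
    foreground_iou,
    predict_slices,
    probability_to_mask,
    train_segmenter,
)


def _small_training_set(n=2, seed=31):
    return sf.make_training_set(
        sf.ScenarioParams(spots_per_cell=20, seed=seed), n
    )


class TestTrainSegmenter:
    def test_held_out_iou_at_ten_stack_scale(self, trained_model):
        """Training on ~10 annotated stacks gives usable masks."""
        assert trained_model.val_iou is not None
        assert trained_model.val_iou >= 0.7

    def test_beats_majority_class_baseline(self, trained_model, zt4_scenario):
        prob = predict_slices(trained_model, zt4_scenario.stack)
        truth = zt4_scenario.gt.cell_mask.labels > 0
        pred = prob >= 0.5
        acc = (pred == truth).mean()
        baseline = max(truth.mean(), 1 - truth.mean())
        assert acc > baseline

    def test_same_seed_identical_weights(self):
        ts = _small_training_set()
        spec = SegModelSpec(iterations=15, seed=5)
        a = train_segmenter(ts, spec)
        b = train_segmenter(ts, spec)
        assert a.checksum() == b.checksum()

    def test_all_background_masks_give_degenerate_model(self):
        ts = _small_training_set(1)
        blank = sf.LabelMask(np.zeros_like(ts[0][1].labels), "cell",
                             ts[0][1].voxel_size_um)
        with pytest.warns(UserWarning, match="background"):
            model = train_segmenter([(ts[0][0], blank)],
                                    SegModelSpec(iterations=1, seed=0))
        assert model.degenerate
        prob = predict_slices(model, ts[0][0])
        assert (prob == 0).all()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], SegModelSpec())

    def test_checkpoint_round_trip(self, trained_model, tmp_path):
        sf.save_segmenter(trained_model, tmp_path / "m.npz")
        back = sf.load_segmenter(tmp_path / "m.npz")
        assert back.checksum() == trained_model.checksum()
        assert back.w_um == trained_model.w_um
        assert back.norm == trained_model.norm
        assert back.val_iou == pytest.approx(trained_model.val_iou)


class TestPredictSlices:
    def test_probabilities_in_range_and_shape(self, trained_model, zt16_scenario):
        prob = predict_slices(trained_model, zt16_scenario.stack)
        assert prob.shape == zt16_scenario.stack.shape_zyx
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_blank_stack_predicts_background(self, trained_model):
        stack = sf.ImageStack(np.zeros((3, 8, 64, 64)),
                              ["marker", "smFISH", "DAPI"], (0.2, 0.05, 0.05))
        prob = predict_slices(trained_model, stack)
        assert (prob < 0.5).mean() > 0.99

    def test_z_reversal_symmetry(self, trained_model, zt16_scenario):
        stack = zt16_scenario.stack
        small = sf.ImageStack(stack.voxels[:, :12, :96, :96].copy(),
                              stack.channel_names, stack.voxel_size_um)
        rev = sf.ImageStack(small.voxels[:, ::-1].copy(),
                            small.channel_names, small.voxel_size_um)
        p = predict_slices(trained_model, small)
        p_rev = predict_slices(trained_model, rev)
        np.testing.assert_allclose(p_rev[::-1], p, atol=1e-10)


class TestProbabilityToMask:
    VOXEL = (0.2, 0.05, 0.05)

    def test_all_zero_probability_empty_mask(self):
        mask = probability_to_mask(np.zeros((4, 8, 8)), self.VOXEL)
        assert mask.label_ids.size == 0

    def test_two_blobs_two_labels(self):
        prob = np.zeros((6, 20, 20))
        prob[1:4, 2:7, 2:7] = 0.9    # 75 voxels
        prob[1:4, 12:18, 12:18] = 0.9  # 108 voxels
        mask = probability_to_mask(prob, self.VOXEL, min_voxels=50)
        assert list(mask.label_ids) == [1, 2]

    def test_small_component_dropped(self):
        prob = np.zeros((6, 10, 10))
        prob[2:4, 2:5, 2:7] = 0.9  # 30 voxels
        mask = probability_to_mask(prob, self.VOXEL, min_voxels=50)
        assert mask.label_ids.size == 0

    def test_probability_range_validated(self):
        with pytest.raises(ValueError):
            probability_to_mask(np.full((2, 2, 2), 1.5), self.VOXEL)


class TestSegmentNuclei:
    def test_recovered_nuclei_overlap_truth(self, zt4_analysis):
        gt_nuc = zt4_analysis.scenario.gt.nucleus_mask
        pred = zt4_analysis.nucleus_mask
        iou = foreground_iou(pred.labels, gt_nuc.labels)
        assert iou is not None and iou >= 0.7

    def test_containment_in_cell_mask(self, zt4_analysis):
        nuc = zt4_analysis.nucleus_mask.labels
        cell = zt4_analysis.cell_mask.labels
        assert not np.any((nuc > 0) & (cell == 0))

    def test_flat_dapi_gives_empty_mask(self, zt4_analysis):
        stack = zt4_analysis.scenario.stack
        flat = sf.ImageStack(stack.voxels.copy(), stack.channel_names,
                             stack.voxel_size_um)
        flat.voxels[flat.channel_index("DAPI")] = 0.0
        nuc = sf.segment_nuclei(flat, "DAPI", zt4_analysis.cell_mask)
        assert nuc.label_ids.size == 0

    def test_missing_dapi_channel_raises(self, zt4_analysis):
        stack = zt4_analysis.scenario.stack
        no_dapi = sf.ImageStack(stack.voxels[:2].copy(),
                                ["marker", "smFISH"], stack.voxel_size_um)
        with pytest.raises(ValueError, match="DAPI"):
            sf.segment_nuclei(no_dapi, "DAPI", zt4_analysis.cell_mask)


class TestMaskGeometry:
    def _sphere_mask(self, radius_um=2.5, voxel=(0.2, 0.05, 0.05)):
        dz, dy, dx = voxel
        nz = int(2 * radius_um / dz) + 4
        ny = nx = int(2 * radius_um / dx) + 4
        zc = ((np.arange(nz) + 0.5) * dz - nz * dz / 2)[:, None, None]
        yc = ((np.arange(ny) + 0.5) * dy - ny * dy / 2)[None, :, None]
        xc = ((np.arange(nx) + 0.5) * dx - nx * dx / 2)[None, None, :]
        inside = zc**2 + yc**2 + xc**2 <= radius_um**2
        return sf.LabelMask(inside.astype(np.int32), "cell", voxel)

    def test_digitized_sphere_equivalent_diameter(self):
        geo = sf.mask_geometry(self._sphere_mask(2.5))
        assert len(geo) == 1
        assert geo[0].equivalent_diameter_um == pytest.approx(5.0, rel=0.03)

    def test_single_voxel_closed_form(self):
        mask = sf.LabelMask(np.ones((1, 1, 1), np.int32), "cell", (1.0, 1.0, 1.0))
        geo = sf.mask_geometry(mask)
        assert geo[0].equivalent_diameter_um == pytest.approx((6 / np.pi) ** (1 / 3))
        assert geo[0].volume_um3 == pytest.approx(1.0)

    def test_equal_voxel_counts_equal_diameters(self):
        labels = np.zeros((4, 6, 6), np.int32)
        labels[0, :2, :3] = 1
        labels[3, 2:4, 3:6] = 2
        geo = sf.mask_geometry(sf.LabelMask(labels, "cell", (0.2, 0.05, 0.05)))
        assert geo[0].equivalent_diameter_um == geo[1].equivalent_diameter_um

    def test_axis_permutation_invariance(self):
        mask = self._sphere_mask(1.0, voxel=(0.1, 0.1, 0.1))
        d0 = sf.mask_geometry(mask)[0].equivalent_diameter_um
        perm = sf.LabelMask(np.transpose(mask.labels, (2, 0, 1)), "cell",
                            (0.1, 0.1, 0.1))
        assert sf.mask_geometry(perm)[0].equivalent_diameter_um == pytest.approx(d0)

    def test_empty_mask_empty_list(self):
        assert sf.mask_geometry(
            sf.LabelMask(np.zeros((2, 2, 2), np.int32), "cell", (1, 1, 1))
        ) == []
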