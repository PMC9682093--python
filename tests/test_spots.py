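"""Spot detection: candidates vs brute force, fitting accuracy, dedupe."""

import numpy as np
import pytest

import smfish3d as sf
from smfish3d.simulate import _render_into
from smfish3d.spots import (
    EstimationError,
    FitFailure,
    Spot,
    SpotCandidate,
    dedupe_spots,
    detect_candidates,
    fit_spot,
    integrated_intensity,
)

from conftest import brute_force_candidates

PSF = sf.PSFParams(sigma_xy=120, sigma_z=400)
VOXEL = (0.2, 0.05, 0.05)


def _stack_from(vol):
    return sf.ImageStack(vol[np.newaxis], ["smFISH"], VOXEL)


def _noiseless_spot(center_um, amplitude=1000.0, background=100.0,
                    shape=(16, 32, 32)):
    vol = np.full(shape, background)
    _render_into(vol, VOXEL, center_um, amplitude, PSF)
    return _stack_from(vol)


class TestDetectCandidates:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.uniform(0, 100, (6, 10, 10))
        stack = _stack_from(vol)
        t = 50.0
        got = sorted(c.index_zyx for c in detect_candidates(stack, 0, t))
        assert got == brute_force_candidates(vol, t)

    def test_equals_brute_force_with_plateaus(self):
        rng = np.random.default_rng(3)
        vol = rng.integers(0, 5, (5, 8, 8)).astype(float)  # many exact ties
        stack = _stack_from(vol)
        got = sorted(c.index_zyx for c in detect_candidates(stack, 0, 2.0))
        assert got == brute_force_candidates(vol, 2.0)

    def test_plateau_tie_broken_lexicographically(self):
        vol = np.zeros((3, 5, 5))
        vol[1, 2, 2] = vol[1, 2, 3] = 10.0  # flat 2-voxel plateau maximum
        got = detect_candidates(_stack_from(vol), 0, 5.0)
        assert [c.index_zyx for c in got] == [(1, 2, 2)]

    def test_single_spot_single_candidate_at_peak(self):
        stack = _noiseless_spot((0.8125, 0.8125, 1.7))  # voxel (8, 16, 16) center
        cands = detect_candidates(stack, 0, 500.0)
        assert len(cands) == 1
        assert cands[0].index_zyx == (8, 16, 16)

    def test_threshold_above_max_gives_empty_list(self):
        stack = _noiseless_spot((0.8, 0.8, 1.7))
        assert detect_candidates(stack, 0, 1e9) == []

    def test_two_separated_spots_two_candidates(self):
        vol = np.full((16, 48, 48), 100.0)
        _render_into(vol, VOXEL, (0.6, 0.6, 1.7), 1000.0, PSF)
        _render_into(vol, VOXEL, (1.8, 1.8, 1.7), 1000.0, PSF)  # >> 4 sigma_xy apart
        cands = detect_candidates(_stack_from(vol), 0, 500.0)
        assert len(cands) == 2

    def test_sorted_by_descending_intensity(self):
        vol = np.zeros((3, 9, 9))
        vol[1, 2, 2] = 5.0
        vol[1, 6, 6] = 9.0
        cands = detect_candidates(_stack_from(vol), 0, 1.0)
        assert [c.intensity for c in cands] == [9.0, 5.0]


class TestFitSpot:
    def test_noiseless_subvoxel_recovery(self):
        # true center offset (dz, dy, dx) = (0.4, -0.2, 0.3) voxels from a center
        base = np.array([1.7, 0.8125, 0.8125])  # z, y, x um of voxel (8,16,16)
        true = (base[2] + 0.3 * 0.05, base[1] - 0.2 * 0.05, base[0] + 0.4 * 0.2)
        stack = _noiseless_spot(true, amplitude=1000.0)
        cand = detect_candidates(stack, 0, 500.0)[0]
        spot = fit_spot(stack, 0, cand, PSF)
        assert isinstance(spot, Spot)
        err_vox = (
            abs(spot.center_um[0] - true[0]) / 0.05,
            abs(spot.center_um[1] - true[1]) / 0.05,
            abs(spot.center_um[2] - true[2]) / 0.2,
        )
        assert max(err_vox) < 0.02
        assert spot.amplitude == pytest.approx(1000.0, rel=0.01)

    def test_background_recovery_at_snr_10(self):
        rng = np.random.default_rng(4)
        vol = np.full((16, 32, 32), 100.0)
        _render_into(vol, VOXEL, (0.8, 0.8, 1.7), 1000.0, PSF)
        noisy = vol + rng.normal(0, 100.0, vol.shape)  # SNR 10
        stack = _stack_from(np.maximum(noisy, 0))
        cand = detect_candidates(stack, 0, 600.0)[0]
        spot = fit_spot(stack, 0, cand, PSF)
        assert isinstance(spot, Spot)
        assert spot.background == pytest.approx(100.0, abs=0.05 * 1000)

    def test_free_sigma_noiseless_recovery(self):
        stack = _noiseless_spot((0.8125, 0.8125, 1.7))
        cand = detect_candidates(stack, 0, 500.0)[0]
        spot = fit_spot(stack, 0, cand, PSF, mode="free_sigma")
        assert spot.sigma_xy_nm == pytest.approx(120, rel=0.01)
        assert spot.sigma_z_nm == pytest.approx(400, rel=0.01)

    def test_integrated_intensity_closed_form(self):
        stack = _noiseless_spot((0.8125, 0.8125, 1.7), amplitude=800.0)
        cand = detect_candidates(stack, 0, 400.0)[0]
        spot = fit_spot(stack, 0, cand, PSF)
        expected = 800.0 * (2 * np.pi) ** 1.5 * 0.12**2 * 0.4
        assert spot.integrated_intensity == pytest.approx(expected, rel=0.01)

    def test_candidate_in_pure_noise_yields_small_amplitude_or_failure(self):
        rng = np.random.default_rng(5)
        vol = 100.0 + rng.normal(0, 10.0, (16, 32, 32))
        stack = _stack_from(vol)
        cands = detect_candidates(stack, 0, 120.0)
        for cand in cands[:5]:
            fit = fit_spot(stack, 0, cand, PSF)
            if isinstance(fit, Spot):
                assert fit.amplitude < 30.0  # within the noise floor
        assert cands  # the scenario actually exercised fits

    def test_window_too_small_fails(self):
        vol = np.ones((1, 2, 2))
        stack = _stack_from(vol)
        fit = fit_spot(stack, 0, SpotCandidate((0, 0, 0), 1.0), PSF)
        assert isinstance(fit, FitFailure)
        assert "window" in fit.reason

    def test_invalid_mode_rejected(self):
        stack = _noiseless_spot((0.8, 0.8, 1.7))
        with pytest.raises(ValueError):
            fit_spot(stack, 0, SpotCandidate((8, 16, 16), 1.0), PSF, mode="magic")


class TestEstimatePSF:
    def test_recovery_within_10pct_at_snr_8(self, isolated_spot_study):
        stack, truth = isolated_spot_study
        psf, report = sf.estimate_psf(stack, 0, truth[["zi", "yi", "xi"]].to_numpy())
        assert psf.sigma_xy == pytest.approx(120, rel=0.10)
        assert psf.sigma_z == pytest.approx(400, rel=0.10)
        assert report["n_used"] >= 45

    def test_noiseless_single_digit_accuracy(self):
        vol = np.full((16, 32, 32), 10.0)
        picks = []
        for k, (y, x) in enumerate([(0.5, 0.5), (0.5, 1.1), (1.1, 0.5)]):
            _render_into(vol, VOXEL, (x, y, 1.7), 1000.0, PSF)
            picks.append((8, int(y / 0.05), int(x / 0.05)))
        stack = _stack_from(vol)
        psf, _ = sf.estimate_psf(stack, 0, picks)
        assert psf.sigma_xy == pytest.approx(120, rel=0.01)
        assert psf.sigma_z == pytest.approx(400, rel=0.01)

    def test_fewer_than_three_picks_rejected(self):
        stack = _noiseless_spot((0.8, 0.8, 1.7))
        with pytest.raises(ValueError, match=">= 3"):
            sf.estimate_psf(stack, 0, [(8, 16, 16), (8, 16, 17)])

    def test_empty_background_picks_raise_estimation_error(self):
        rng = np.random.default_rng(6)
        stack = _stack_from(100 + rng.normal(0, 1e-3, (16, 32, 32)))
        with pytest.warns(UserWarning):
            with pytest.raises(EstimationError):
                sf.estimate_psf(stack, 0, [(8, 8, 8), (8, 16, 16), (8, 24, 24)])


def _spot_at(x, y, z, amp):
    return Spot((x, y, z), amp, 0.0, 120.0, 400.0,
                integrated_intensity(amp, 0.12, 0.4))


class TestDedupeSpots:
    def test_identical_centers_merge_keeping_brighter(self):
        out = dedupe_spots([_spot_at(1, 1, 1, 500), _spot_at(1, 1, 1, 800)], PSF)
        assert len(out) == 1
        assert out[0].amplitude == 800

    def test_five_sigma_apart_both_kept(self):
        out = dedupe_spots(
            [_spot_at(1, 1, 1, 500), _spot_at(1 + 5 * 0.12, 1, 1, 400)], PSF
        )
        assert len(out) == 2

    def test_chain_of_three_keeps_brightest_survivor(self):
        # each within 1 scaled sigma of the next; greedy by amplitude
        chain = [
            _spot_at(1.00, 1, 1, 500),
            _spot_at(1.08, 1, 1, 900),
            _spot_at(1.16, 1, 1, 700),
        ]
        out = dedupe_spots(chain, PSF)
        assert [s.amplitude for s in out] == [900]

    def test_anisotropic_metric(self):
        # dz = 0.3 um is 2.5 lateral sigmas but only 0.75 axial sigmas
        out = dedupe_spots([_spot_at(1, 1, 1, 500), _spot_at(1, 1, 1.3, 400)], PSF)
        assert len(out) == 1

    def test_matches_brute_force_pairwise_merge(self):
        rng = np.random.default_rng(7)
        spots = [
            _spot_at(rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 2),
                     rng.uniform(100, 1000))
            for _ in range(40)
        ]
        out = dedupe_spots(spots, PSF)
        # brute force: same greedy suppression by descending amplitude
        def dist(a, b):
            return np.sqrt(
                ((a.center_um[0] - b.center_um[0]) ** 2
                 + (a.center_um[1] - b.center_um[1]) ** 2) / 0.12**2
                + (a.center_um[2] - b.center_um[2]) ** 2 / 0.4**2
            )
        expected = []
        for s in sorted(spots, key=lambda s: -s.amplitude):
            if all(dist(s, k) >= 1.0 for k in expected):
                expected.append(s)
        assert sorted(s.amplitude for s in out) == sorted(
            s.amplitude for s in expected
        )
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                assert dist(a, b) >= 1.0


class TestDetectSpots:
    def test_recall_and_precision_on_planted_scenario(self, zt4_analysis):
        """80 planted spots/cell at the detector's working point."""
        from scipy.spatial import cKDTree

        table = zt4_analysis.table  # detected at T = median + 3 robust SD
        det = table.df[["x_um", "y_um", "z_um"]].to_numpy()
        tru = zt4_analysis.scenario.gt.spots[["x_um", "y_um", "z_um"]].to_numpy()
        scale = np.array([0.12, 0.12, 0.4])
        d_dt, i_dt = cKDTree(tru / scale).query(det / scale)
        precision = (d_dt < 2).mean()
        recall = len(set(i_dt[d_dt < 2])) / len(tru)
        assert precision >= 0.95
        assert recall >= 0.95

    def test_count_monotone_in_threshold(self):
        """10-point threshold sweep: detected count never increases with T."""
        rng = np.random.default_rng(10)
        vol = np.full((12, 64, 64), 100.0)
        for k in range(10):
            _render_into(
                vol, VOXEL,
                (0.5 + (k % 5) * 0.55, 0.7 + (k // 5) * 1.3, 1.2),
                rng.uniform(60, 400), PSF,
            )
        stack = _stack_from(np.maximum(vol + rng.normal(0, 10, vol.shape), 0))
        med = np.median(stack.channel(0))
        counts = [
            len(sf.detect_spots(stack, 0, t, PSF))
            for t in np.linspace(med + 30, stack.channel(0).max() + 1, 10)
        ]
        assert counts[0] > 0
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_empty_channel_gives_empty_table(self):
        rng = np.random.default_rng(8)
        stack = _stack_from(100 + rng.normal(0, 5, (12, 32, 32)))
        table = sf.detect_spots(stack, 0, 5.0, PSF, threshold_mode="mad")
        assert len(table) == 0

    def test_parameters_recorded(self, zt16_analysis):
        params = zt16_analysis.table.params
        assert params["threshold"] == 3.0
        assert params["threshold_mode"] == "mad"
        assert params["sigma_xy_nm"] == 120.0


class TestParameterRecovery:
    def test_center_and_sigma_recovery_at_snr_10(self):
        """Median center error < 0.1 voxel; widths unbiased within 5%."""
        stack, truth = sf.simulate_isolated_spots(100, snr=10.0, seed=9)
        errs, sxy, sz = [], [], []
        for _, s in truth.iterrows():
            cand = SpotCandidate((int(s.zi), int(s.yi), int(s.xi)), 0.0)
            fit = fit_spot(stack, 0, cand, PSF, mode="free_sigma")
            if isinstance(fit, FitFailure):
                continue
            errs.append(
                max(
                    abs(fit.center_um[0] - s.x_um) / 0.05,
                    abs(fit.center_um[1] - s.y_um) / 0.05,
                    abs(fit.center_um[2] - s.z_um) / 0.2,
                )
            )
            sxy.append(fit.sigma_xy_nm)
            sz.append(fit.sigma_z_nm)
        assert len(errs) >= 90
        assert np.median(errs) < 0.1
        assert np.mean(sxy) == pytest.approx(120, rel=0.05)
        assert np.mean(sz) == pytest.approx(400, rel=0.05)
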