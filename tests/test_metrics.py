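"""Schedule and image-quality metrics."""

import numpy as np
import pytest

from stoscan.control import (
    AcquisitionSchedule,
    STO200_PROTOCOL,
    STO600_PROTOCOL,
    ideal_schedule,
)
from stoscan.grids import GridSpec, Volume3D
from stoscan.adaptive import DVF
from stoscan.metrics import (
    TIWProbe,
    cnr,
    dose_reduction,
    interbin_separation,
    motion_robustness,
    schedule_mae,
    tiw,
)


def schedule_from_angles(angles, bins=None):
    n = len(angles)
    return AcquisitionSchedule(
        np.arange(1, n + 1), np.arange(n) * 0.5, np.asarray(angles, float),
        np.asarray(bins if bins is not None else np.ones(n), np.int64),
        np.ones(n, bool))


class TestScheduleMae:
    @pytest.mark.parametrize("acq,ideal,expected", [
        ([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], 0.0),
        ([1.0, 2.0, 3.0], [0.0, 1.0, 2.0], 1.0),
        ([0.5, 1.0, 2.5], [0.0, 1.0, 2.0], 1.0 / 3.0),
    ])
    def test_values(self, acq, ideal, expected):
        assert schedule_mae(schedule_from_angles(acq),
                            schedule_from_angles(ideal)) \
            == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            schedule_mae(schedule_from_angles([0.0, 1.0]),
                         schedule_from_angles([0.0, 1.0, 2.0]))

    def test_zero_iff_identical(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.random(50)) * 200
        assert schedule_mae(schedule_from_angles(a),
                            schedule_from_angles(a)) == 0.0
        assert schedule_mae(schedule_from_angles(a + 0.01),
                            schedule_from_angles(a)) > 0


class TestInterbinSeparation:
    def test_ideal_sto200_gaps_are_ten_degrees(self):
        gaps = interbin_separation(ideal_schedule(STO200_PROTOCOL))
        for g in gaps.values():
            np.testing.assert_allclose(g, 10.0, atol=1e-9)

    def test_ideal_sto600_gaps(self):
        gaps = interbin_separation(ideal_schedule(STO600_PROTOCOL))
        for g in gaps.values():
            np.testing.assert_allclose(g, 200.0 / 60.0, atol=1e-9)

    def test_single_projection_per_bin_gives_empty_lists(self):
        s = schedule_from_angles([0.0, 10.0, 20.0], bins=[1, 2, 3])
        gaps = interbin_separation(s)
        assert all(g == [] for g in gaps.values())


class TestCnr:
    def test_formula(self):
        vol = Volume3D(np.zeros((10, 10, 10), np.float32), (1, 1, 1),
                       (0, 0, 0))
        vol.voxels[:5] = 100.0
        vol.voxels[5:] = 50.0
        lung = np.zeros(vol.voxels.shape, bool)
        lung[:5] = True
        assert cnr(vol, lung, ~lung) == pytest.approx(2.0)

    def test_identical_rois_give_zero_contrast(self):
        vol = Volume3D(np.full((8, 8, 8), 3.0, np.float32), (1, 1, 1),
                       (0, 0, 0))
        a = np.zeros(vol.voxels.shape, bool)
        a[:4] = True
        assert cnr(vol, a, ~a) == 0.0

    def test_gaussian_sampling_distribution(self):
        rng = np.random.default_rng(42)
        vals = []
        for _ in range(30):
            v = np.zeros((10, 10, 10))
            lung = np.zeros((10, 10, 10), bool)
            lung[:5] = True
            v[lung] = 0.02 + 0.01 * rng.standard_normal(500)
            v[~lung] = 0.05 + 0.01 * rng.standard_normal(500)
            vol = Volume3D(v, (1, 1, 1), (0, 0, 0))
            vals.append(cnr(vol, lung, ~lung))
        # pooled sigma includes the between-class spread:
        # sqrt(0.01^2 + 0.015^2) ~ 0.018 -> CNR ~ -1.66
        expect = -0.03 / np.sqrt(0.01 ** 2 + 0.015 ** 2)
        assert np.mean(vals) == pytest.approx(expect, abs=0.3)

    def test_empty_or_overlapping_rois_rejected(self):
        vol = Volume3D(np.zeros((4, 4, 4), np.float32), (1, 1, 1), (0, 0, 0))
        empty = np.zeros((4, 4, 4), bool)
        full = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError):
            cnr(vol, empty, full)
        with pytest.raises(ValueError):
            cnr(vol, full, full)


def logistic_volume(scale, n=60, spacing=2.0):
    x = np.arange(n)
    prof = 0.01 + 0.02 / (1.0 + np.exp(-(x - n / 2) / scale))
    vox = np.tile(prof, (5, 5, 1)).astype(np.float32)
    return Volume3D(vox, (spacing,) * 3, (0, 0, 0))


class TestTiw:
    @pytest.mark.parametrize("scale", [1.0, 2.0, 4.0])
    def test_recovers_logistic_width(self, scale):
        vol = logistic_volume(scale)
        w, n_failed = tiw(vol, TIWProbe((2, 2, 30), axis=2, n_perp=5,
                                        n_along=60))
        expect = np.log(81.0) * scale * 2.0
        assert n_failed == 0
        assert abs(w - expect) / expect < 0.02

    def test_step_edge_within_two_voxels(self):
        vox = np.zeros((5, 5, 60), np.float32)
        vox[:, :, 30:] = 0.03
        vol = Volume3D(vox, (2, 2, 2), (0, 0, 0))
        w, _ = tiw(vol, TIWProbe((2, 2, 30), axis=2, n_perp=5, n_along=60))
        assert w <= 2 * 2.0

    def test_monotone_in_blur(self):
        from scipy.ndimage import gaussian_filter1d

        widths = []
        base = logistic_volume(1.0)
        for sigma in (0.0, 1.5, 3.0):
            v = gaussian_filter1d(base.voxels.astype(float), sigma, axis=2) \
                if sigma else base.voxels
            vol = Volume3D(v, base.spacing, base.origin)
            widths.append(tiw(vol, TIWProbe((2, 2, 30), axis=2, n_perp=5,
                                            n_along=60))[0])
        assert widths[0] < widths[1] < widths[2]

    def test_no_coherent_interface_rejected(self):
        rng = np.random.default_rng(0)
        vol = Volume3D(rng.standard_normal((5, 5, 60)).astype(np.float32),
                       (2, 2, 2), (0, 0, 0))
        with pytest.raises(ValueError, match="interface"):
            tiw(vol, TIWProbe((2, 2, 30), axis=2, n_perp=5, n_along=60))

    def test_probe_outside_volume_rejected(self):
        vol = logistic_volume(2.0)
        with pytest.raises(ValueError, match="outside"):
            tiw(vol, TIWProbe((2, 2, 5), axis=2, n_perp=5, n_along=60))


class TestDoseReduction:
    @pytest.mark.parametrize("n,ref,expected", [
        (600, 1320, 54.5), (200, 1320, 84.8), (1320, 1320, 0.0)])
    def test_values(self, n, ref, expected):
        assert dose_reduction(n, ref) == pytest.approx(expected, abs=0.05)

    def test_rounds_to_paper_integers(self):
        assert round(dose_reduction(600, 1320)) == 55
        assert round(dose_reduction(200, 1320)) == 85

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            dose_reduction(100, 0)


class TestMotionRobustness:
    def test_identical_images_small_displacement(self, model, grid):
        from stoscan.phantom import phantom_volume

        vol = phantom_volume(model, 0.5, grid)
        mask = vol.voxels > 0.028
        out = motion_robustness(vol, vol, mask)
        assert out["mean_total_mm"] < 0.5 * min(grid.spacing)

    def test_known_shift_recovered(self, model, grid):
        from scipy.ndimage import shift as ndshift
        from stoscan.phantom import phantom_volume

        ref = phantom_volume(model, 0.5, grid)
        mc = Volume3D(ndshift(ref.voxels.astype(float),
                              (0, 0, 3.0 / grid.spacing[2]), order=1,
                              mode="nearest"), grid.spacing, grid.origin)
        ax = grid.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        tc = model.tumor_center(0.5)
        mask = ((X - tc[0]) ** 2 + (Y - tc[1]) ** 2
                + (Z - tc[2]) ** 2) <= model.tumor.radius ** 2
        out = motion_robustness(mc, ref, mask)
        assert out["mean_total_mm"] == pytest.approx(3.0, abs=grid.spacing[2])

    def test_statistics_use_mask_only(self, grid):
        rng = np.random.default_rng(0)
        vecs = rng.standard_normal((*grid.shape, 3))
        dvf = DVF(vecs, grid.spacing, grid.origin)
        mask = np.zeros(grid.shape, bool)
        mask[20:30, 20:30, 20:30] = True
        dummy = Volume3D(np.zeros(grid.shape, np.float32), grid.spacing,
                         grid.origin)
        out1 = motion_robustness(dummy, dummy, mask, dvf=dvf)
        vecs2 = vecs.copy()
        vecs2[~mask] = 99.0
        out2 = motion_robustness(dummy, dummy, mask,
                                 dvf=DVF(vecs2, grid.spacing, grid.origin))
        assert out1 == out2
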