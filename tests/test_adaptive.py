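"""McKinnon-Bates reconstruction, deformable registration and DVF algebra."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as ndshift

from stoscan.adaptive import (
    DVF,
    RegConfig,
    RegistrationError,
    adaptive_reconstruct,
    affine_scale,
    invert_dvf,
    mkb_reconstruct,
    register_deformable,
    simulate_bin_projections,
    warp_volume,
)
from stoscan.grids import GridSpec, Volume3D
from stoscan.phantom import phantom_volume
from stoscan.projector import reconstruct_4dfdk
from tests.conftest import nrms


class TestAffineScale:
    def test_identity(self, sphere_volume):
        ab = affine_scale(sphere_volume, sphere_volume)
        assert ab.offset == pytest.approx(0.0, abs=1e-12)
        assert ab.gain == pytest.approx(1.0)

    def test_exact_affine_relation(self, sphere_volume):
        target = sphere_volume.like(2 * sphere_volume.voxels + 3)
        ab = affine_scale(sphere_volume, target)
        # inputs are float32 volumes, so exactness is at single precision
        assert ab.gain == pytest.approx(2.0, abs=1e-4)
        assert ab.offset == pytest.approx(3.0, abs=1e-4)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        g = GridSpec((8, 8, 8), (1, 1, 1))
        s = Volume3D(rng.random(g.shape), g.spacing, g.origin)
        t = Volume3D(rng.random(g.shape), g.spacing, g.origin)
        ab = affine_scale(s, t)
        A = np.column_stack([np.ones(s.voxels.size),
                             s.voxels.astype(np.float64).ravel()])
        coef, *_ = np.linalg.lstsq(A, t.voxels.astype(np.float64).ravel(),
                                   rcond=None)
        assert abs(ab.offset - coef[0]) < 1e-10
        assert abs(ab.gain - coef[1]) < 1e-10

    def test_constant_source_fallback(self):
        g = GridSpec((4, 4, 4), (1, 1, 1))
        s = Volume3D(np.full(g.shape, 2.0), g.spacing, g.origin)
        t = Volume3D(np.full(g.shape, 5.0), g.spacing, g.origin)
        ab = affine_scale(s, t)
        assert ab.degenerate
        assert ab.gain == 1.0
        assert ab.offset == pytest.approx(3.0)


class TestSimulateBinProjections:
    def test_zero_volume_zero_projections(self, grid, geometry,
                                          static_projections):
        out = simulate_bin_projections(Volume3D.zeros(grid),
                                       static_projections)
        assert all(np.all(v.stack == 0) for v in out.values())

    def test_angles_match_per_bin(self, static_fdk, static_projections):
        out = simulate_bin_projections(static_fdk, static_projections)
        for j, sub in out.items():
            np.testing.assert_array_equal(
                sub.angles_deg, static_projections.for_bin(j).angles_deg)

    def test_static_scan_reprojections_close(self, static_fdk,
                                             static_projections):
        out = simulate_bin_projections(static_fdk, static_projections)
        j = 1
        d_j = static_projections.for_bin(j)
        rel = nrms(out[j].stack, d_j.stack)
        assert rel < 0.25  # within the reconstruction's self-consistency


class TestMkb:
    def test_zero_data_zero_frames(self, grid, geometry, static_projections):
        zero = static_projections.replace_stack(
            np.zeros_like(static_projections.stack))
        img = mkb_reconstruct(zero, 10, grid)
        assert all(np.all(f.voxels == 0) for f in img.frames)

    def test_static_frames_match_fdk(self, grid, static_projections,
                                     static_fdk):
        img = mkb_reconstruct(static_projections, 10, grid)
        worst = max(nrms(f.voxels, static_fdk.voxels) for f in img.frames)
        assert worst < 0.05

    def test_moving_streak_reduction(self, grid, sto200_sim):
        d = sto200_sim.projections
        img4 = reconstruct_4dfdk(d, 10, grid)
        mkb = mkb_reconstruct(d, 10, grid)
        g = grid
        ax = g.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        roi = (X ** 2 + (Y - 70) ** 2 + Z ** 2) <= 14 ** 2
        wins = 0
        for j in range(1, 11):
            rel4 = (img4.frame(j).voxels[roi].std()
                    / max(img4.frame(j).voxels[roi].mean(), 1e-9))
            relm = (mkb.frame(j).voxels[roi].std()
                    / max(mkb.frame(j).voxels[roi].mean(), 1e-9))
            wins += (relm < rel4)
        assert wins >= 8


class TestRegistration:
    def test_identity_registration_is_tiny(self, model, grid):
        vol = phantom_volume(model, 0.5, grid)
        V = register_deformable(vol, vol)
        p95 = np.percentile(V.magnitude(), 95)
        assert p95 < 0.5 * min(grid.spacing)

    def test_recovers_known_translation(self, model, grid):
        fixed = phantom_volume(model, 0.5, grid)
        shifted = ndshift(fixed.voxels.astype(float),
                          (0, 0, 6.0 / grid.spacing[2]), order=1,
                          mode="nearest")
        moving = Volume3D(shifted, grid.spacing, grid.origin)
        V = register_deformable(moving, fixed)
        body = fixed.voxels > 0.003
        err = np.sqrt(((V.vectors[body] - np.array([0.0, 0.0, 6.0])) ** 2)
                      .sum(axis=1)).mean()
        assert err < 1.5

    def test_pure_noise_converges(self, grid):
        rng = np.random.default_rng(0)
        a = Volume3D(rng.random(grid.shape).astype(np.float32),
                     grid.spacing, grid.origin)
        b = Volume3D(rng.random(grid.shape).astype(np.float32),
                     grid.spacing, grid.origin)
        V = register_deformable(a, b)  # quality not asserted
        assert np.all(np.isfinite(V.vectors))

    def test_mismatched_grids_rejected(self, grid):
        a = Volume3D(np.zeros((8, 8, 8)), (1, 1, 1), (0, 0, 0))
        b = Volume3D(np.zeros((9, 8, 8)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            register_deformable(a, b)


class TestDvfAlgebra:
    def test_zero_field_inverts_to_zero(self, grid):
        V = DVF.zero(grid)
        assert np.all(invert_dvf(V).vectors == 0)

    def test_constant_translation_inverts_exactly(self, grid):
        t = np.array([3.0, -2.0, 5.0])
        V = DVF(np.tile(t, (*grid.shape, 1)), grid.spacing, grid.origin)
        Vi = invert_dvf(V)
        interior = tuple(slice(4, -4) for _ in range(3))
        got = Vi.vectors[interior]
        np.testing.assert_allclose(got, np.broadcast_to(-t, got.shape),
                                   atol=1e-6)

    def test_smooth_field_composition_residual(self, grid):
        rng = np.random.default_rng(0)
        vecs = np.stack([gaussian_filter(rng.standard_normal(grid.shape), 6)
                         for _ in range(3)], axis=-1)
        vecs *= 2 * min(grid.spacing) / np.abs(vecs).max()
        V = DVF(vecs, grid.spacing, grid.origin)
        Vi = invert_dvf(V)
        from scipy.ndimage import map_coordinates

        idx = np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij")
        coords = [idx[i] + V.vectors[..., i] / grid.spacing[i]
                  for i in range(3)]
        comp = np.empty_like(vecs)
        for i in range(3):
            comp[..., i] = V.vectors[..., i] + map_coordinates(
                Vi.vectors[..., i], coords, order=1, mode="nearest")
        mag_vox = np.sqrt((comp ** 2).sum(-1)) / min(grid.spacing)
        assert np.percentile(mag_vox, 95) < 0.2

    def test_warp_zero_field_is_identity(self, sphere_volume, grid):
        out = warp_volume(sphere_volume, DVF.zero(grid))
        np.testing.assert_array_equal(out.voxels, sphere_volume.voxels)

    def test_warp_translation_moves_sphere(self, sphere_volume, grid):
        t = np.array([0.0, 0.0, 8.0])
        V = DVF(np.tile(t, (*grid.shape, 1)), grid.spacing, grid.origin)
        out = warp_volume(sphere_volume, V)
        ax = grid.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")

        def com_z(v):
            w = np.maximum(v.voxels, 0.0)
            return float((w * Z).sum() / w.sum())

        # pull-back by +t shifts the image content by -t
        assert com_z(out) - com_z(sphere_volume) == pytest.approx(
            -8.0, abs=0.5 * grid.spacing[2])

    def test_warp_linear_in_intensities(self, sphere_volume, grid):
        rng = np.random.default_rng(2)
        vecs = np.stack([gaussian_filter(rng.standard_normal(grid.shape), 5)
                         for _ in range(3)], axis=-1) * 5.0
        V = DVF(vecs, grid.spacing, grid.origin)
        w1 = warp_volume(sphere_volume, V)
        w2 = warp_volume(sphere_volume.like(3 * sphere_volume.voxels), V)
        np.testing.assert_allclose(w2.voxels, 3 * w1.voxels, rtol=1e-5,
                                   atol=1e-6)


class TestAdaptive:
    def test_static_frames_match_fdk(self, grid, static_projections,
                                     static_fdk):
        img = adaptive_reconstruct(static_projections, 10, None, grid)
        worst = max(nrms(f.voxels, static_fdk.voxels) for f in img.frames)
        assert worst < 0.05

    def test_frame_count_and_bins_preserved(self, grid, static_projections):
        img = adaptive_reconstruct(static_projections, 10, None, grid)
        assert img.n_bins == 10
        assert img.bins == list(range(1, 11))
        assert all(f.grid == img.frames[0].grid for f in img.frames)

    def test_missing_reference_bin_rejected(self, grid, static_projections):
        cfg = RegConfig(reference_bin=42)
        with pytest.raises(ValueError, match="reference bin"):
            adaptive_reconstruct(static_projections, 10, cfg, grid)

    def test_reference_frame_is_mean_with_zero_fields(self, grid,
                                                      static_projections):
        # static data: all fields snap to zero and the reference adaptive
        # frame equals the mean of the MKB frames (== the reference MKB
        # frame up to the per-bin sampling residual)
        mkb = mkb_reconstruct(static_projections, 10, grid)
        img, dvfs = adaptive_reconstruct(static_projections, 10, None, grid,
                                         return_dvfs=True)
        if all(np.all(v.vectors == 0) for v in dvfs.values()):
            mean = np.mean([f.voxels for f in mkb.frames], axis=0)
            np.testing.assert_allclose(img.frame(1).voxels, mean, atol=1e-5)
        assert nrms(img.frame(1).voxels, mkb.frame(1).voxels) < 0.05
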