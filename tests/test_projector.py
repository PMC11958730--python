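"""Cone-beam forward projection, FDK filtering and reconstruction."""

import numpy as np
import pytest

from stoscan.grids import GridSpec, ProjectionSet, ScanGeometry, Volume3D
from stoscan.projector import (
    back_project,
    fdk_filter,
    forward_project,
    reconstruct_4dfdk,
    reconstruct_fdk,
)
from tests.conftest import nrms


def chord_length(geometry, u_mm, v_mm, radius):
    """Analytic chord of a centered sphere along a source-pixel ray."""
    src = np.array([geometry.sad, 0.0, 0.0])
    pix = np.array([geometry.sad - geometry.sdd, u_mm, v_mm])
    d = pix - src
    d = d / np.linalg.norm(d)
    rho = np.linalg.norm(np.cross(-src, d))
    if rho >= radius:
        return 0.0
    return 2.0 * np.sqrt(radius ** 2 - rho ** 2)


class TestForwardProject:
    def test_zero_volume_gives_zero_projections(self, geometry, grid):
        ps = forward_project(Volume3D.zeros(grid), geometry, [0.0, 45.0])
        assert np.all(ps.stack == 0)

    def test_sphere_matches_chord_length_oracle(self, geometry,
                                                sphere_volume):
        ps = forward_project(sphere_volume, geometry, [0.0])
        p = ps.stack[0]
        u = geometry.det_u()
        v = geometry.det_v()
        mu, R = 0.02, 50.0
        # central ray (between the four center pixels)
        central = p[47:49, 47:49].mean()
        expect = mu * 2 * R
        assert abs(central - expect) / expect < 0.02
        # off-axis rays at moderate impact parameter
        for ir, ic in [(47, 40), (40, 47), (44, 42), (47, 36)]:
            expect = mu * chord_length(geometry, u[ic], v[ir], R)
            rho = chord_length(geometry, u[ic], v[ir], R)
            assert expect > 0
            got = p[ir, ic]
            assert abs(got - expect) / expect < 0.03

    def test_linearity_in_attenuation(self, geometry, sphere_volume):
        ps1 = forward_project(sphere_volume, geometry, [30.0])
        ps2 = forward_project(sphere_volume.like(2 * sphere_volume.voxels),
                              geometry, [30.0])
        np.testing.assert_allclose(ps2.stack, 2 * ps1.stack, rtol=1e-5,
                                   atol=1e-7)

    def test_out_of_fov_warns(self, geometry):
        g = GridSpec((32, 32, 8), (16.0, 16.0, 4.0))
        vol = Volume3D(np.ones(g.shape, np.float32) * 0.01, g.spacing,
                       g.origin)
        with pytest.warns(UserWarning, match="field of view"):
            forward_project(vol, geometry, [0.0])


class TestFdkFilter:
    def test_zero_in_zero_out(self, geometry):
        ps = ProjectionSet(np.zeros((3, 96, 96), np.float32),
                           [0.0, 50.0, 100.0], geometry)
        out = fdk_filter(ps)
        assert np.all(out.stack == 0)

    def test_linearity(self, geometry):
        rng = np.random.default_rng(0)
        a = rng.random((4, 96, 96)).astype(np.float32)
        b = rng.random((4, 96, 96)).astype(np.float32)
        angles = [0.0, 60.0, 120.0, 180.0]
        fa = fdk_filter(ProjectionSet(a, angles, geometry)).stack
        fb = fdk_filter(ProjectionSet(b, angles, geometry)).stack
        fab = fdk_filter(ProjectionSet(2 * a + 3 * b, angles,
                                       geometry)).stack
        np.testing.assert_allclose(fab, 2 * fa + 3 * fb, rtol=1e-4,
                                   atol=1e-5)

    def test_ramp_kills_dc_on_constant_rows(self, geometry):
        # use a mid-arc projection where the short-scan weight is unity
        ps = ProjectionSet(np.ones((2, 96, 96), np.float32), [0.0, 100.0],
                           geometry)
        out = fdk_filter(ps).stack[1]
        assert np.abs(out).max() > 0
        # away from the row edges the ramp response is tiny relative to
        # the unit input (only the smooth cosine-weight bump survives)
        interior = out[:, 20:76]
        assert np.abs(interior).max() < 0.005
        # while the row edges carry the expected ramp overshoot
        assert np.abs(out[:, :4]).max() > 5 * np.abs(interior).max()

    def test_insufficient_arc_rejected(self):
        geo = ScanGeometry(arc_deg=150.0)
        ps = ProjectionSet(np.ones((2, 96, 96), np.float32), [0.0, 100.0],
                           geo)
        with pytest.raises(ValueError, match="short-scan"):
            fdk_filter(ps)


class TestBackProject:
    def test_zero_projections_zero_volume(self, geometry, grid):
        ps = ProjectionSet(np.zeros((2, 96, 96), np.float32), [0.0, 90.0],
                           geometry)
        vol = back_project(ps, geometry, grid)
        assert np.all(vol.voxels == 0)

    def test_adjoint_consistency(self, geometry):
        # <A x, p> == <x, A^T p> for the unweighted pair
        g = GridSpec((16, 16, 16), (8.0, 8.0, 8.0))
        rng = np.random.default_rng(7)
        x = Volume3D(rng.random(g.shape).astype(np.float32), g.spacing,
                     g.origin)
        angles = [10.0, 100.0, 170.0]
        p = rng.random((3, geometry.det_rows, geometry.det_cols)) \
            .astype(np.float32)
        ax = forward_project(x, geometry, angles)
        atp = back_project(ProjectionSet(p, angles, geometry), geometry, g,
                           weighting="adjoint")
        lhs = float(np.sum(ax.stack.astype(np.float64) * p))
        rhs = float(np.sum(x.voxels.astype(np.float64)
                           * atp.voxels.astype(np.float64)))
        assert abs(lhs - rhs) / abs(lhs) < 0.01

    def test_single_projection_constant_along_rays(self, geometry):
        # one backprojected view varies slowly along the source direction
        g = GridSpec((32, 32, 4), (8.0, 8.0, 8.0))
        p = np.zeros((1, geometry.det_rows, geometry.det_cols), np.float32)
        p[0, 47:49, 47:49] = 1.0
        vol = back_project(ProjectionSet(p, [0.0], geometry), geometry, g,
                           weighting="fdk")
        v = vol.voxels[:, :, 2]
        # the lit stripe runs along x (source at +x for angle 0)
        lit = np.nonzero(v.max(axis=0) > 0.25 * v.max())[0]
        assert lit.size <= 4  # confined to the central columns


class TestReconstruct:
    def test_static_sphere_center_and_value(self, geometry, grid,
                                            sphere_volume):
        angles = np.arange(200) * 1.0 + 0.5
        ps = forward_project(sphere_volume, geometry, angles)
        rec = reconstruct_fdk(ps, grid)
        ax = grid.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        inner = np.sqrt(X ** 2 + Y ** 2 + Z ** 2) <= 30
        assert abs(rec.voxels[inner].mean() - 0.02) / 0.02 < 0.15
        thr = rec.voxels > 0.5 * rec.voxels.max()
        com = [float(np.mean(c[thr])) for c in (X, Y, Z)]
        assert np.all(np.abs(com) < grid.spacing[0])

    def test_linearity_in_data(self, geometry, grid, static_projections):
        d1 = static_projections
        rec1 = reconstruct_fdk(d1, grid)
        rec2 = reconstruct_fdk(d1.replace_stack(2 * d1.stack), grid)
        np.testing.assert_allclose(rec2.voxels, 2 * rec1.voxels, rtol=1e-4,
                                   atol=1e-6)

    def test_sum_identity_quick(self, geometry, static_projections):
        # exact decomposition on a reduced grid (the acceptance suite
        # repeats this at the full default grid)
        g = GridSpec((32, 32, 32), (8.0, 8.0, 8.0))
        rec = reconstruct_fdk(static_projections, g)
        img = reconstruct_4dfdk(static_projections, 10, g)
        total = np.sum([f.voxels for f in img.frames], axis=0)
        assert nrms(total, rec.voxels) < 1e-6

    def test_single_bin_equals_fdk(self, geometry, grid, static_projections):
        d = static_projections.select(np.arange(static_projections.n_proj))
        d.bins = np.ones(d.n_proj, np.int64)
        img = reconstruct_4dfdk(d, 1, grid)
        rec = reconstruct_fdk(d, grid)
        np.testing.assert_allclose(img.frames[0].voxels, rec.voxels,
                                   atol=1e-6)

    def test_empty_bin_rejected(self, geometry, grid, static_projections):
        with pytest.raises(ValueError, match="bin 11"):
            reconstruct_4dfdk(static_projections, 11, grid)

    def test_static_frames_pairwise_similar(self, grid, static_projections):
        img = reconstruct_4dfdk(static_projections, 10, grid)
        f0 = img.frames[0].voxels
        for f in img.frames[1:]:
            assert nrms(f.voxels, f0) < 0.35  # sampling differences only
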