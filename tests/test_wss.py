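import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import venoflow as vf
from venoflow import (
    SurfaceVectorSeries,
    Waveform,
    osi,
    sample_on_mesh,
    spatial_mean,
    tawss,
    wall_shear_vectors,
    womersley_velocity,
)
from tests.conftest import constant_series


@pytest.fixture(scope="module")
def poiseuille_series(blood):
    """WSS recovered from an exact Poiseuille field on a fine cylinder."""
    surf, vol = vf.make_cylinder(0.25, 1.0, 64)
    sampler = womersley_velocity(0.25, Waveform.constant(5.0, 0.5, 10), blood)
    field = sample_on_mesh(sampler, vol, [0.0, 0.25])
    return surf, vol, wall_shear_vectors(field, vol, surf, blood)


def lateral_nodes(surf, radius=0.25, z_lo=0.2, z_hi=0.8):
    r = np.linalg.norm(surf.nodes[:, :2], axis=1)
    z = surf.nodes[:, 2]
    return (np.abs(r - radius) < 1e-9) & (z > z_lo) & (z < z_hi)


class TestWallShearVectors:
    def test_poiseuille_magnitude_recovered(self, poiseuille_series, blood):
        surf, _, series = poiseuille_series
        exact = vf.poiseuille_wss(5.0, 0.25, blood)
        tau = np.linalg.norm(series.vectors[0], axis=1)
        sel = lateral_nodes(surf)
        assert np.abs(tau[sel] - exact).max() < 0.03 * exact

    def test_tangential_to_surface(self, poiseuille_series):
        surf, _, series = poiseuille_series
        normals = surf.node_normals()
        tau = series.vectors[0]
        mags = np.linalg.norm(tau, axis=1)
        sel = lateral_nodes(surf)
        dots = np.abs(np.einsum("ij,ij->i", tau, normals))
        assert (dots[sel] / mags[sel]).max() < 1e-6

    def test_zero_velocity_gives_zero_wss(self, small_cylinder, blood):
        surf, vol = small_cylinder
        field = vf.TimeSeriesField(
            mesh=vol, phases=[0.0, 0.5], vectors=np.zeros((2, vol.n_nodes, 3))
        )
        series = wall_shear_vectors(field, vol, surf, blood)
        assert np.all(series.vectors == 0.0)


class TestTawss:
    def test_steady_series_returns_magnitude(self, flat_patch):
        series = constant_series(flat_patch, (3.0, 4.0, 0.0))
        assert np.allclose(tawss(series).values, 5.0)

    def test_alternating_equal_magnitudes(self, flat_patch):
        n = flat_patch.n_nodes
        vecs = np.zeros((2, n, 3))
        vecs[0, :, 0] = 1.0
        vecs[1, :, 0] = -1.0
        series = SurfaceVectorSeries(flat_patch, np.array([0.0, 0.5]), vecs, period=1.0)
        assert np.allclose(tawss(series).values, 1.0)

    def test_rotating_constant_magnitude(self, flat_patch):
        n = flat_patch.n_nodes
        t = np.arange(8) / 8
        vecs = np.stack(
            [
                np.column_stack(
                    [
                        5 * np.cos(2 * np.pi * tk) * np.ones(n),
                        5 * np.sin(2 * np.pi * tk) * np.ones(n),
                        np.zeros(n),
                    ]
                )
                for tk in t
            ]
        )
        series = SurfaceVectorSeries(flat_patch, t, vecs, period=1.0)
        assert np.allclose(tawss(series).values, 5.0)

    def test_rotation_invariance(self, flat_patch):
        rng = np.random.default_rng(0)
        n = flat_patch.n_nodes
        vecs = rng.normal(size=(5, n, 3))
        t = np.arange(5) / 5
        base = tawss(SurfaceVectorSeries(flat_patch, t, vecs, period=1.0)).values
        ang = 1.1
        R = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        rot_mesh = flat_patch.transformed(R, np.zeros(3))
        rot = tawss(
            SurfaceVectorSeries(rot_mesh, t, vecs @ R.T, period=1.0)
        ).values
        assert np.allclose(rot, base, rtol=1e-9)

    def test_single_phase_rejected(self, flat_patch):
        series = constant_series(flat_patch, (1, 0, 0), phases=(0.0,))
        with pytest.raises(ValueError):
            tawss(series)


class TestOsi:
    def test_steady_is_zero(self, flat_patch):
        assert np.all(osi(constant_series(flat_patch, (1.0, 0, 0))).values == 0.0)

    def test_full_reversal_is_half(self, flat_patch):
        n = flat_patch.n_nodes
        vecs = np.zeros((2, n, 3))
        vecs[0, :, 0] = 1.0
        vecs[1, :, 0] = -1.0
        series = SurfaceVectorSeries(flat_patch, np.array([0.0, 0.5]), vecs, period=1.0)
        assert np.allclose(osi(series).values, 0.5)

    def test_orthogonal_half_cycles(self, flat_patch):
        n = flat_patch.n_nodes
        vecs = np.zeros((2, n, 3))
        vecs[0, :, 0] = 1.0
        vecs[1, :, 1] = 1.0
        series = SurfaceVectorSeries(flat_patch, np.array([0.0, 0.5]), vecs, period=1.0)
        expected = 0.5 * (1 - np.sqrt(2) / 2)
        assert np.allclose(osi(series).values, expected, atol=1e-6)

    def test_zero_field_warns_and_returns_zero(self, flat_patch):
        series = constant_series(flat_patch, (0.0, 0.0, 0.0))
        with pytest.warns(UserWarning):
            assert np.all(osi(series).values == 0.0)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_on_random_series(self, flat_patch, seed):
        rng = np.random.default_rng(seed)
        n = flat_patch.n_nodes
        vecs = rng.normal(size=(10, n, 3)) * rng.lognormal(size=(10, n, 1))
        t = np.arange(10) / 10
        vals = osi(SurfaceVectorSeries(flat_patch, t, vecs, period=1.0)).values
        assert np.all(vals >= 0.0)
        assert np.all(vals <= 0.5)


class TestSpatialMean:
    def test_constant_field_is_exact(self, small_cylinder):
        surf, _ = small_cylinder
        field = vf.ScalarSurfaceField(surf, np.full(surf.n_nodes, 3.7))
        roi = vf.RegionOfInterest(np.arange(surf.n_triangles))
        assert spatial_mean(field, roi) == pytest.approx(3.7)

    def test_linear_field_on_band_gives_midpoint(self):
        surf, _ = vf.make_cylinder(0.25, 2.0, 32)
        roi = vf.clip_roi(
            surf,
            vf.PlaneSection((0, 0, 0.5), (0, 0, 1)),
            vf.PlaneSection((0, 0, 1.5), (0, 0, 1)),
        )
        field = vf.ScalarSurfaceField(surf, surf.nodes[:, 2].copy())
        assert spatial_mean(field, roi) == pytest.approx(1.0, rel=0.02)

    def test_bounded_by_nodal_extremes(self, small_cylinder):
        surf, _ = small_cylinder
        rng = np.random.default_rng(1)
        vals = rng.uniform(2.0, 9.0, surf.n_nodes)
        field = vf.ScalarSurfaceField(surf, vals)
        roi = vf.RegionOfInterest(np.arange(0, surf.n_triangles, 3))
        m = spatial_mean(field, roi)
        sel = np.unique(surf.triangles[roi.triangle_ids])
        assert vals[sel].min() <= m <= vals[sel].max()


class TestBilateralSymmetryNull:
    def test_mirror_symmetric_branches_agree(self, blood):
        """Identical straight outflow channels with the same Womersley inflow
        produce WSSmean agreeing well inside the 1.3-fold similarity band."""
        w = vf.synth_waveform(4.0, 0.4, period=0.5, seed=11)
        sides = []
        for sign in (+1.0, -1.0):
            surf, vol = vf.make_cylinder(0.2, 1.5, 24)
            R = np.diag([sign, 1.0, sign])  # mirror through the y-z plane
            surf_m = surf.transformed(R, np.zeros(3))
            vol_m = vol.transformed(R, np.zeros(3))
            sampler = womersley_velocity(
                0.2, w, blood, origin=(0, 0, 0), direction=(0, 0, sign)
            )
            field = sample_on_mesh(sampler, vol_m, 0.5 * np.arange(8) / 8)
            series = wall_shear_vectors(field, vol_m, surf_m, blood)
            roi = vf.RegionOfInterest(np.flatnonzero(surf_m.boundary_id == 0))
            sides.append(spatial_mean(tawss(series), roi))
        ratio = max(sides) / min(sides)
        assert ratio < 1.02
        assert ratio < 1.3
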