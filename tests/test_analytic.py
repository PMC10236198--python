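import numpy as np
import pytest

import venoflow as vf
from venoflow import (
    FluidProperties,
    Waveform,
    lamb_oseen_swirl,
    planted_surface_field,
    poiseuille_wss,
    sample_on_mesh,
    womersley_number,
    womersley_velocity,
)


class TestPoiseuilleWss:
    def test_worked_example(self, blood):
        # 4 * 0.04 * 5 / (pi * 0.25^3)
        assert poiseuille_wss(5.0, 0.25, blood) == pytest.approx(16.297, abs=1e-3)

    def test_zero_flow(self, blood):
        assert poiseuille_wss(0.0, 0.25, blood) == 0.0

    def test_cubic_radius_scaling(self, blood):
        assert poiseuille_wss(5.0, 0.5, blood) == pytest.approx(
            poiseuille_wss(5.0, 0.25, blood) / 8.0
        )

    def test_rejects_zero_radius(self, blood):
        with pytest.raises(ValueError):
            poiseuille_wss(5.0, 0.0, blood)


class TestWomersleyNumber:
    def test_neonatal_example(self, blood):
        # R 0.25 cm at HR 138 bpm (omega = 2 pi * 2.3 Hz)
        assert womersley_number(0.25, 2 * np.pi * 2.3, blood) == pytest.approx(
            4.89, abs=0.01
        )

    def test_zero_frequency(self, blood):
        assert womersley_number(0.25, 0.0, blood) == 0.0

    def test_linear_in_radius(self, blood):
        a1 = womersley_number(0.25, 10.0, blood)
        assert womersley_number(0.5, 10.0, blood) == pytest.approx(2 * a1)


class TestWomersleyVelocity:
    def test_constant_waveform_gives_parabola(self, blood):
        R = 0.25
        sampler = womersley_velocity(R, Waveform.constant(5.0, 0.5, 10), blood)
        u_center = sampler(np.array([[0.0, 0.0, 0.3]]), 0.0)[0, 2]
        u_mean = 5.0 / (np.pi * R**2)
        assert u_center == pytest.approx(2 * u_mean, rel=1e-4)
        # parabolic shape at half radius
        u_half = sampler(np.array([[R / 2, 0.0, 0.3]]), 0.0)[0, 2]
        assert u_half == pytest.approx(2 * u_mean * 0.75, rel=1e-4)

    def test_low_alpha_limit_is_quasi_steady(self, blood):
        R = 0.25
        nu = blood.kinematic_viscosity
        omega = (0.1 / R) ** 2 * nu  # alpha = 0.1
        T = 2 * np.pi / omega
        t = T * np.arange(10) / 10
        w = Waveform(t, 5.0 * (1 + 0.5 * np.sin(2 * np.pi * t / T)), T)
        sampler = womersley_velocity(R, w, blood)
        r = np.linspace(0, 0.99 * R, 15)
        pts = np.column_stack([r, np.zeros_like(r), np.zeros_like(r)])
        for tq in np.linspace(0.0, T, 5):
            u = sampler(pts, tq)[:, 2]
            q = 5.0 * (1 + 0.5 * np.sin(2 * np.pi * tq / T))
            parab = 2 * q / (np.pi * R**2) * (1 - (r / R) ** 2)
            assert np.abs(u - parab).max() < 0.01 * np.abs(parab).max()

    def test_flux_reproduces_waveform(self, blood):
        R = 0.25
        w = vf.synth_waveform(5.0, 0.8, period=0.5, seed=1)
        sampler = womersley_velocity(R, w, blood)
        nq = 64
        # equal-area radial quadrature
        rq = np.sqrt((np.arange(nq) + 0.5) / nq) * R
        pts = np.column_stack([rq, np.zeros(nq), np.zeros(nq)])
        for tq in (0.05, 0.21, 0.4):
            flux = sampler(pts, tq)[:, 2].mean() * np.pi * R**2
            assert flux == pytest.approx(float(w.evaluate(tq)[0]), rel=0.01)

    def test_no_slip_at_the_wall(self, blood):
        R = 0.25
        w = vf.synth_waveform(5.0, 0.8, period=0.5, seed=4)
        sampler = womersley_velocity(R, w, blood)
        wall = np.array([[R, 0.0, 0.1], [0.0, R, 0.9]])
        center_scale = abs(sampler(np.array([[0, 0, 0.5]]), 0.1)[0, 2])
        assert np.abs(sampler(wall, 0.1)).max() < 1e-10 * center_scale

    def test_high_alpha_profile_is_blunt(self, blood):
        R = 0.25
        nu = blood.kinematic_viscosity
        omega = (10.0 / R) ** 2 * nu  # alpha = 10
        T = 2 * np.pi / omega
        t = T * np.arange(10) / 10
        w = Waveform(t, 5.0 + 2.0 * np.sin(2 * np.pi * t / T), T)
        sampler = womersley_velocity(R, w, blood)
        # oscillatory component: strip the steady part by differencing phases
        r = np.linspace(0, 0.95 * R, 30)
        pts = np.column_stack([r, np.zeros_like(r), np.zeros_like(r)])
        u1 = sampler(pts, 0.0)[:, 2]
        u2 = sampler(pts, T / 2)[:, 2]
        osc = np.abs(u1 - u2)
        # blunt core: centerline amplitude not the 2x of a parabola
        assert osc[0] / osc.mean() < 1.6


class TestLambOseen:
    def test_axis_velocity_is_axial(self):
        s = lamb_oseen_swirl(10.0, 0.1, axial_speed=3.0)
        v = s(np.array([[0.0, 0.0, 2.0]]), 0.0)[0]
        assert np.allclose(v, [0, 0, 3.0])

    def test_azimuthal_profile_at_core_radius(self):
        gamma, rc = 10.0, 0.1
        s = lamb_oseen_swirl(gamma, rc)
        v = s(np.array([[rc, 0.0, 0.0]]), 0.0)[0]
        expected = gamma / (2 * np.pi * rc) * (1 - np.exp(-1.0))
        assert np.linalg.norm(v) == pytest.approx(expected, abs=1e-6)
        # pure azimuthal direction (+y at +x)
        assert v[0] == pytest.approx(0.0, abs=1e-12)
        assert v[1] == pytest.approx(expected, rel=1e-9)

    def test_two_distant_vortices_have_two_swirl_centers(self):
        a = lamb_oseen_swirl(10.0, 0.05, origin=(1.0, 0, 0))
        b = lamb_oseen_swirl(10.0, 0.05, origin=(-1.0, 0, 0))
        s = a + b
        from scipy.optimize import fsolve

        for guess in ([1.0, 0.0], [-1.0, 0.0]):
            def transverse(xy):
                v = s(np.array([[xy[0], xy[1], 0.0]]), 0.0)[0]
                return [v[0], v[1]]

            root = fsolve(transverse, guess, full_output=False)
            assert np.linalg.norm(np.asarray(root) - np.asarray(guess)) < 0.01

    def test_discretely_divergence_free(self):
        s = lamb_oseen_swirl(10.0, 0.2, axial_speed=1.0)
        h = 1e-4
        pts = np.array([[0.3, 0.1, 0.0], [0.05, -0.02, 1.0], [0.0, 0.25, -2.0]])
        for p in pts:
            div = 0.0
            for k in range(3):
                e = np.zeros(3)
                e[k] = h
                div += (s((p + e)[None], 0.0)[0, k] - s((p - e)[None], 0.0)[0, k]) / (
                    2 * h
                )
            shear = np.linalg.norm(s(p[None], 0.0)[0]) / 0.2
            assert abs(div) < 1e-3 * max(shear, 1.0)


class TestPlantedSurfaceField:
    @pytest.mark.parametrize("pattern", sorted(vf.analytic.PATTERN_MATRICES))
    def test_zero_is_unique_and_at_plant(self, flat_patch, pattern):
        series = planted_surface_field(flat_patch, pattern, location=(0, 0, 0))
        mags = np.linalg.norm(series.vectors[0], axis=1)
        idx = int(np.argmin(np.linalg.norm(flat_patch.nodes, axis=1)))
        assert mags[idx] == 0.0
        others = np.delete(mags, idx)
        assert others.min() > 0

    @pytest.mark.parametrize(
        "pattern,radial_sign", [("source-node", 1.0), ("sink-node", -1.0)]
    )
    def test_local_canonical_form_of_nodes(self, flat_patch, pattern, radial_sign):
        # the node patterns are v = +/- (x, y) locally: parallel to the radial
        # direction with the requested sign
        series = planted_surface_field(flat_patch, pattern, location=(0, 0, 0))
        r = np.linalg.norm(flat_patch.nodes, axis=1)
        near = (r > 0) & (r < 0.5)
        v = series.vectors[0][near]
        xy = flat_patch.nodes[near]
        cross_z = v[:, 0] * xy[:, 1] - v[:, 1] * xy[:, 0]
        assert np.allclose(cross_z, 0.0, atol=1e-12)
        assert np.all(radial_sign * np.einsum("ij,ij->i", v, xy) > 0)

    def test_saddle_canonical_form(self, flat_patch):
        series = planted_surface_field(flat_patch, "saddle", location=(0, 0, 0))
        r = np.linalg.norm(flat_patch.nodes, axis=1)
        near = (r > 0) & (r < 0.5)
        v = series.vectors[0][near]
        xy = flat_patch.nodes[near]
        scale = v[np.argmax(np.abs(xy[:, 0]))][0] / xy[np.argmax(np.abs(xy[:, 0]))][0]
        assert np.allclose(v[:, 0], scale * xy[:, 0], atol=1e-12)
        assert np.allclose(v[:, 1], -scale * xy[:, 1], atol=1e-12)

    def test_none_pattern_is_nowhere_zero(self, flat_patch):
        series = planted_surface_field(flat_patch, "none", background=(1.0, 0, 0))
        assert np.linalg.norm(series.vectors[0], axis=1).min() > 0

    def test_off_mesh_location_rejected(self, flat_patch):
        with pytest.raises(ValueError):
            planted_surface_field(flat_patch, "saddle", location=(50.0, 0, 0))


class TestSampleOnMesh:
    def test_constant_sampler(self, small_cylinder):
        _, vol = small_cylinder
        s = vf.VelocitySampler(lambda p, t: np.tile([1.0, 2.0, 3.0], (len(p), 1)))
        f = sample_on_mesh(s, vol, [0.0, 0.1])
        assert np.allclose(f.vectors, [1.0, 2.0, 3.0])

    def test_poiseuille_no_slip_at_wall_nodes(self, small_cylinder, blood):
        surf, vol = small_cylinder
        sampler = womersley_velocity(0.25, Waveform.constant(5.0, 0.5, 10), blood)
        f = sample_on_mesh(sampler, vol, [0.0])
        wall_r = np.linalg.norm(vol.nodes[vol.wall_map][:, :2], axis=1)
        lateral = np.abs(wall_r - 0.25) < 1e-9
        assert np.abs(f.vectors[0][vol.wall_map][lateral]).max() < 1e-12

    def test_linear_field_sampled_exactly(self, small_cylinder):
        _, vol = small_cylinder
        s = vf.VelocitySampler(
            lambda p, t: np.column_stack([p[:, 2], p[:, 0], -p[:, 1]])
        )
        f = sample_on_mesh(s, vol, [0.0])
        expected = np.column_stack(
            [vol.nodes[:, 2], vol.nodes[:, 0], -vol.nodes[:, 1]]
        )
        assert np.array_equal(f.vectors[0], expected)

    def test_empty_phases_rejected(self, small_cylinder):
        _, vol = small_cylinder
        s = vf.VelocitySampler(lambda p, t: np.zeros_like(p))
        with pytest.raises(ValueError):
            sample_on_mesh(s, vol, [])
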