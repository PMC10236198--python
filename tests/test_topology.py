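import numpy as np
import pytest

import venoflow as vf
from venoflow import (
    SurfaceVectorSeries,
    Waveform,
    classify_critical_point,
    corelen_mean,
    extract_core_lines,
    find_critical_points,
    lamb_oseen_swirl,
    n_critical_points_mean,
    planted_surface_field,
    sample_on_mesh,
    womersley_velocity,
)
from venoflow.geometry import TetVolumeMesh


class TestClassifier:
    @pytest.mark.parametrize(
        "J,cls,index",
        [
            ([[1, 0], [0, 1]], "source node", 1),
            ([[-2, 0], [0, -1]], "sink node", 1),
            ([[1, 0], [0, -1]], "saddle", -1),
            ([[1, -1], [1, 1]], "source focus", 1),
            ([[-1, -1], [1, -1]], "sink focus", 1),
            ([[0, -3], [3, 0]], "center", 1),
        ],
    )
    def test_canonical_jacobians(self, J, cls, index):
        got_cls, got_index = classify_critical_point(np.array(J, float))
        assert got_cls == cls
        assert got_index == index

    def test_singular_jacobian_is_degenerate(self):
        cls, index = classify_critical_point(np.array([[1.0, 0.0], [2.0, 0.0]]))
        assert cls == "degenerate"
        assert index == 0


class TestPlantedDetection:
    @pytest.mark.parametrize(
        "pattern,cls,index",
        [
            ("source-node", "source node", 1),
            ("sink-node", "sink node", 1),
            ("source-focus", "source focus", 1),
            ("sink-focus", "sink focus", 1),
            ("saddle", "saddle", -1),
        ],
    )
    def test_all_five_classes_round_trip(self, flat_patch, pattern, cls, index):
        """Plant -> detect -> classify recovers location, class and index;
        the planted zero sits at a grid node shared by several elements and
        must be reported once."""
        series = planted_surface_field(flat_patch, pattern, location=(0, 0, 0))
        cps = find_critical_points(series, 0)
        assert len(cps) == 1
        cp = cps[0]
        assert np.linalg.norm(np.asarray(cp.position)) < 1e-6
        assert cp.cls == cls
        assert cp.poincare_index == index

    def test_interior_plant_located_exactly(self, flat_patch):
        # plant at an off-node location snaps to the nearest node; detection
        # recovers that node to within 1e-6 cm
        target = flat_patch.nodes[137]
        series = planted_surface_field(flat_patch, "saddle", location=tuple(target))
        cps = find_critical_points(series, 0)
        assert len(cps) == 1
        assert np.linalg.norm(np.asarray(cps[0].position) - target) < 1e-6

    def test_nowhere_zero_field_yields_nothing(self, flat_patch):
        series = planted_surface_field(flat_patch, "none", background=(1.0, 0.5, 0))
        assert find_critical_points(series, 0) == []

    def test_detection_restricted_to_roi(self, flat_patch):
        series = planted_surface_field(flat_patch, "source-node", location=(0, 0, 0))
        # ROI far from the plant
        cents = flat_patch.triangle_centroids()
        far = np.flatnonzero(cents[:, 0] > 0.5)
        roi = vf.RegionOfInterest(far)
        assert find_critical_points(series, 0, roi=roi) == []


class TestPoincareHopf:
    @staticmethod
    def projected_constant_field(mesh, c):
        normals = mesh.node_normals()
        c = np.asarray(c, float)
        c = c / np.linalg.norm(c)
        v = c[None, :] - (normals @ c)[:, None] * normals
        return SurfaceVectorSeries(
            mesh=mesh, phases=np.array([0.0]), vectors=v[None]
        )

    @staticmethod
    def brute_force_windings(mesh, series, n_edge=60):
        """Independent oracle: the winding number of the in-plane field around
        each element boundary, sampled densely edge by edge.  A nonzero
        winding certifies an enclosed zero and equals its Poincare index,
        without using the detector's linear solve or the classifier."""
        tri = mesh.triangles
        pts = mesh.nodes[tri]
        vecs = series.vectors[0][tri]
        n_zeros = 0
        index_sum = 0
        for m in range(len(tri)):
            p, v = pts[m], vecs[m]
            b1 = p[1] - p[0]
            b1 = b1 / np.linalg.norm(b1)
            nrm = np.cross(p[1] - p[0], p[2] - p[0])
            nrm = nrm / np.linalg.norm(nrm)
            b2 = np.cross(nrm, b1)
            v2 = v @ np.column_stack([b1, b2])
            samples = []
            for a, b in ((0, 1), (1, 2), (2, 0)):
                ts = np.arange(n_edge) / n_edge
                samples.append(np.outer(1 - ts, v2[a]) + np.outer(ts, v2[b]))
            s = np.vstack(samples)
            ang = np.arctan2(s[:, 1], s[:, 0])
            d = np.diff(np.concatenate([ang, ang[:1]]))
            d = (d + np.pi) % (2 * np.pi) - np.pi
            w = int(round(d.sum() / (2 * np.pi)))
            if w != 0:
                n_zeros += 1
                index_sum += w
        return n_zeros, index_sum

    @pytest.mark.parametrize(
        "maker,chi",
        [
            ("sphere", 2),
            ("torus", 0),
        ],
    )
    def test_index_sum_equals_euler_characteristic(self, maker, chi):
        import trimesh

        if maker == "sphere":
            tm = trimesh.creation.icosphere(subdivisions=3)
        else:
            tm = trimesh.creation.torus(
                major_radius=2.0, minor_radius=0.7, major_sections=48, minor_sections=24
            )
        mesh = vf.TriSurfaceMesh(
            nodes=np.asarray(tm.vertices, float), triangles=np.asarray(tm.faces)
        )
        series = self.projected_constant_field(mesh, (0.31, 0.17, 0.93))
        cps = find_critical_points(series, 0)
        assert sum(cp.poincare_index for cp in cps) == chi
        # combinatorial Euler characteristic agrees
        n_edges = len(
            {tuple(sorted(e)) for t in mesh.triangles for e in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0]))}
        )
        assert mesh.n_nodes - n_edges + mesh.n_triangles == chi
        # brute-force winding enumeration agrees on both count and index sum
        bf_zeros, bf_index_sum = self.brute_force_windings(mesh, series)
        assert bf_zeros == len(cps)
        assert bf_index_sum == chi


class TestCountMeans:
    def test_point_in_every_phase(self, flat_patch):
        series = planted_surface_field(
            flat_patch, "source-node", location=(0, 0, 0), phases=np.arange(4) / 4
        )
        assert n_critical_points_mean(series) == 1.0

    def test_point_in_half_the_phases(self, flat_patch):
        present = planted_surface_field(flat_patch, "saddle", location=(0, 0, 0))
        absent = planted_surface_field(flat_patch, "none", background=(1.0, 0, 0))
        vecs = np.concatenate([present.vectors] * 5 + [absent.vectors] * 5)
        series = SurfaceVectorSeries(
            flat_patch, np.arange(10) / 10, vecs, period=1.0
        )
        assert n_critical_points_mean(series) == 0.5

    def test_alternating_two_and_one(self, flat_patch):
        # v = (x^2 - 1/4, y): exactly two zeros, a saddle at (-1/2, 0) and a
        # source node at (1/2, 0), both mesh nodes of the patch
        x, y = flat_patch.nodes[:, 0], flat_patch.nodes[:, 1]
        two_vec = np.column_stack([x**2 - 0.25, y, np.zeros_like(x)])[None]
        one = planted_surface_field(flat_patch, "saddle", location=(-0.5, 0.0, 0))
        vecs = np.concatenate(
            [one.vectors if k % 2 == 0 else two_vec for k in range(10)]
        )
        series = SurfaceVectorSeries(flat_patch, np.arange(10) / 10, vecs, period=1.0)
        assert n_critical_points_mean(series) == 1.5


class TestCoreLines:
    def test_axial_vortex_in_long_cylinder(self):
        _, vol = vf.make_cylinder(0.5, 10.0, 16)
        swirl = lamb_oseen_swirl(10.0, 0.15, axial_speed=5.0)
        field = sample_on_mesh(swirl, vol, [0.0])
        lines = extract_core_lines(field, vol, 0)
        assert lines.n_lines == 1
        assert lines.total_length == pytest.approx(10.0, rel=0.02)

    def test_poiseuille_has_no_core_lines(self, blood):
        _, vol = vf.make_cylinder(0.5, 10.0, 16)
        sampler = womersley_velocity(0.5, Waveform.constant(5.0, 0.5, 10), blood)
        field = sample_on_mesh(sampler, vol, [0.0])
        lines = extract_core_lines(field, vol, 0)
        assert lines.total_length == 0.0

    def test_two_parallel_vortices(self):
        _, v1 = vf.make_cylinder(0.3, 10.0, 24)
        eye = np.eye(3)
        va = v1.transformed(eye, np.array([0.4, 0.0, 0.0]))
        vb = v1.transformed(eye, np.array([-0.4, 0.0, 0.0]))
        vol = TetVolumeMesh(
            nodes=np.vstack([va.nodes, vb.nodes]),
            tets=np.vstack([va.tets, vb.tets + va.n_nodes]),
        )
        a = lamb_oseen_swirl(10.0, 0.05, 3.0, origin=(0.4, 0, 0))
        b = lamb_oseen_swirl(10.0, 0.05, 3.0, origin=(-0.4, 0, 0))
        field = sample_on_mesh(a + b, vol, [0.0])
        lines = extract_core_lines(field, vol, 0)
        assert lines.n_lines == 2
        assert lines.total_length == pytest.approx(20.0, rel=0.03)

    def test_irrotational_strain_has_no_core_lines(self, small_cylinder):
        _, vol = small_cylinder
        s = vf.VelocitySampler(
            lambda p, t: np.column_stack([p[:, 0], -p[:, 1], np.zeros(len(p))])
        )
        field = sample_on_mesh(s, vol, [0.0])
        assert extract_core_lines(field, vol, 0).total_length == 0.0


class TestCorelenMean:
    def test_steady_vortex_equals_single_phase(self):
        _, vol = vf.make_cylinder(0.5, 5.0, 16)
        swirl = lamb_oseen_swirl(10.0, 0.15, axial_speed=5.0)
        field = sample_on_mesh(swirl, vol, [0.0, 0.25, 0.5, 0.75])
        single = extract_core_lines(field, vol, 0).total_length
        assert corelen_mean(field, vol) == pytest.approx(single)

    def test_vortex_half_the_phases(self):
        _, vol = vf.make_cylinder(0.5, 5.0, 16)
        swirl = lamb_oseen_swirl(10.0, 0.15, axial_speed=5.0)
        on = sample_on_mesh(swirl, vol, [0.0]).vectors
        off = np.zeros_like(on)
        vecs = np.concatenate([on, off])
        field = vf.TimeSeriesField(mesh=vol, phases=[0.0, 0.5], vectors=vecs)
        single = extract_core_lines(field, vol, 0).total_length
        assert corelen_mean(field, vol) == pytest.approx(single / 2)

    def test_zero_field(self, small_cylinder):
        _, vol = small_cylinder
        field = vf.TimeSeriesField(
            mesh=vol, phases=[0.0, 0.5], vectors=np.zeros((2, vol.n_nodes, 3))
        )
        assert corelen_mean(field, vol) == 0.0


class TestRefinementStability:
    def test_planted_count_stable_under_refinement(self):
        for res in (8, 16, 32):
            patch = vf.make_flat_patch(2.0, 2.0, res)
            series = planted_surface_field(patch, "source-focus", location=(0, 0, 0))
            assert len(find_critical_points(series, 0)) == 1
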