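"""Centerline resampling, rotation-minimizing frames, tube meshing and
diameter-stenosis profiling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sws4d as s
from sws4d.errors import InvalidGeometryError

from conftest import straight_frame


class TestResampleCenterline:
    def test_straight_segment_uniform_spacing(self):
        pts = [(0, 0, 0), (0, 0, 10)]
        cl = s.resample_centerline(pts, 5)
        assert np.allclose(cl.points[:, 2], [0, 2.5, 5, 7.5, 10])
        assert np.allclose(cl.points[:, :2], 0.0)

    def test_idempotent_on_equally_spaced_input(self):
        pts = np.column_stack([np.zeros(7), np.linspace(0, 6, 7), np.linspace(0, 12, 7)])
        out = s.resample_centerline(pts, 7)
        assert np.allclose(out.points, pts, atol=1e-12)

    def test_quarter_circle_spacing_matches_arclength_oracle(self):
        # dense polyline of a radius-10 quarter circle; chord-sum oracle
        t = np.linspace(0.0, np.pi / 2.0, 100)
        dense = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)])
        cl = s.resample_centerline(dense, 5)
        chord_arc = np.sum(np.linalg.norm(np.diff(dense, axis=0), axis=1))
        # arclength spacing = (π·10/2)/4 ≈ 3.927 mm per segment
        assert chord_arc / 4.0 == pytest.approx(np.pi * 10 / 8, rel=1e-4)
        # consecutive outputs are separated by equal straight-line chords of
        # that arc: 2·R·sin(arc / 2R)
        gaps = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        assert np.allclose(gaps, 2 * 10 * np.sin(np.pi / 16), rtol=1e-3)

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(20, 3)), axis=0)
        cl = s.resample_centerline(pts, 9)
        assert np.allclose(cl.points[0], pts[0])
        assert np.allclose(cl.points[-1], pts[-1])

    def test_degenerate_input_rejected(self):
        with pytest.raises(InvalidGeometryError):
            s.resample_centerline([(1.0, 1.0, 1.0)] * 5, 5)


class TestLocalFrames:
    def test_straight_line_constant_frames(self):
        cl = s.Centerline(points=np.column_stack([np.zeros(9), np.zeros(9), np.arange(9.0)]))
        t, n1, n2 = s.local_frames(cl)
        assert np.allclose(t, t[0])
        assert np.allclose(n1, n1[0])
        for a, b in ((t, n1), (t, n2), (n1, n2)):
            assert np.max(np.abs(np.einsum("ij,ij->i", a, b))) < 1e-10

    def test_planar_arc_normal_stays_in_plane(self):
        ang = np.linspace(0.0, 1.2, 40)
        pts = np.column_stack([10 * np.cos(ang), np.zeros_like(ang), 10 * np.sin(ang)])
        _, n1, _ = s.local_frames(s.Centerline(points=pts))
        # the transported normal must never leave the x-z plane of the curve
        assert np.max(np.abs(n1[:, 1])) < 1e-10

    def test_agrees_with_double_reflection_oracle(self):
        # independent rotation-minimizing-frame construction (double
        # reflection) must agree with the transported frames on a smooth curve
        ang = np.linspace(0.0, 1.2, 200)
        pts = np.column_stack([10 * np.cos(ang), 2 * np.sin(2 * ang), 10 * np.sin(ang)])
        cl = s.Centerline(points=pts)
        tan, n1, _ = s.local_frames(cl)
        ref = n1[0].copy()
        dr = [ref]
        for i in range(len(pts) - 1):
            v1 = pts[i + 1] - pts[i]
            c1 = v1 @ v1
            rl = dr[-1] - (2.0 / c1) * (v1 @ dr[-1]) * v1
            tl = tan[i] - (2.0 / c1) * (v1 @ tan[i]) * v1
            v2 = tan[i + 1] - tl
            c2 = v2 @ v2
            nxt = rl if c2 < 1e-30 else rl - (2.0 / c2) * (v2 @ rl) * v2
            nxt = nxt - (nxt @ tan[i + 1]) * tan[i + 1]
            dr.append(nxt / np.linalg.norm(nxt))
        assert np.max(np.linalg.norm(n1 - np.array(dr), axis=1)) < 1e-3

    def test_helix_accumulates_no_twist(self):
        # rotation-minimizing frames must not spin about the tangent on a
        # torsion-heavy curve; measure per-step twist of normal1
        t = np.linspace(0.0, 4.0 * np.pi, 400)
        pts = np.column_stack([5 * np.cos(t), 5 * np.sin(t), 2.0 * t])
        tan, n1, n2 = s.local_frames(s.Centerline(points=pts))
        twists = []
        for i in range(len(pts) - 1):
            # exact parallel transport: rotate n1[i] about tan[i] × tan[i+1]
            # by the angle between the tangents, then compare with n1[i+1]
            axis = np.cross(tan[i], tan[i + 1])
            sin_a = np.linalg.norm(axis)
            cos_a = np.dot(tan[i], tan[i + 1])
            if sin_a < 1e-15:
                v = n1[i]
            else:
                axis = axis / sin_a
                v = (
                    n1[i] * cos_a
                    + np.cross(axis, n1[i]) * sin_a
                    + axis * np.dot(axis, n1[i]) * (1.0 - cos_a)
                )
            twists.append(
                np.arctan2(np.dot(np.cross(v, n1[i + 1]), tan[i + 1]), np.dot(v, n1[i + 1]))
            )
        assert np.max(np.abs(twists)) < 1e-6

    def test_orthonormality(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(0.5 + rng.random(size=(30, 3)), axis=0)
        t, n1, n2 = s.local_frames(s.Centerline(points=pts))
        for arr in (t, n1, n2):
            assert np.allclose(np.linalg.norm(arr, axis=1), 1.0, atol=1e-10)
        assert np.allclose(np.einsum("ij,ij->i", t, n1), 0.0, atol=1e-10)
        assert np.allclose(np.cross(t, n1), n2, atol=1e-9)


class TestBuildStructuredMesh:
    def test_straight_cylinder_nodes_on_surface(self):
        mesh = s.build_structured_mesh(straight_frame(radius=1.5), L=11, C=16)
        dist = np.linalg.norm(mesh.nodes[..., :2], axis=-1)
        assert np.allclose(dist, 1.5, atol=1e-12)

    def test_deterministic(self):
        f = straight_frame()
        m1 = s.build_structured_mesh(f, L=21, C=12)
        m2 = s.build_structured_mesh(f, L=21, C=12)
        assert np.array_equal(m1.nodes, m2.nodes)

    def test_torus_arc_node_to_centerline_distance(self):
        # tube r=1 bent around radius 10: every node at distance 1 from the
        # analytic circle (equally spaced exact circle points, L = n so the
        # centerline passes through the mesh rings unperturbed)
        L = 40
        ang = np.linspace(0.0, 1.0, L)
        pts = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang), np.zeros_like(ang)])
        frame = s.VesselFrame(
            centerline=s.Centerline(points=pts), ring_radius=np.ones(L), phase="diastasis"
        )
        mesh = s.build_structured_mesh(frame, L=L, C=16)
        nodes = mesh.nodes.reshape(-1, 3)
        rho = np.linalg.norm(nodes[:, :2], axis=1)
        dist_to_circle = np.sqrt((rho - 10.0) ** 2 + nodes[:, 2] ** 2)
        assert np.max(np.abs(dist_to_circle - 1.0)) < 1e-9

    def test_self_intersection_warns(self):
        ang = np.linspace(0.0, 2.0, 120)
        pts = np.column_stack([2 * np.cos(ang), 2 * np.sin(ang), np.zeros_like(ang)])
        frame = s.VesselFrame(
            centerline=s.Centerline(points=pts), ring_radius=np.full(120, 2.5), phase="diastasis"
        )
        with pytest.warns(RuntimeWarning, match="self-intersect"):
            mesh = s.build_structured_mesh(frame, L=30, C=16)
        assert mesh.self_intersecting

    def test_mesh_round_trip(self, stenotic_vessel):
        mesh = s.build_structured_mesh(stenotic_vessel.lumen, L=101, C=32)
        back = s.mesh_to_frame(mesh)
        assert np.allclose(back.ring_radius, stenotic_vessel.lumen.ring_radius, atol=1e-9)
        assert np.allclose(
            back.centerline.points, stenotic_vessel.lumen.centerline.points, atol=1e-6
        )


class TestStenosisProfile:
    def test_uniform_vessel_all_normal(self):
        prof = s.compute_stenosis_profile(straight_frame())
        assert np.allclose(prof.percent_ds, 0.0)
        assert not prof.stenotic.any()

    def test_fifty_percent_lesion(self, stenotic_vessel):
        prof = s.compute_stenosis_profile(stenotic_vessel.lumen)
        assert prof.percent_ds.max() == pytest.approx(50.0, abs=0.5)
        assert prof.labels[prof.throat_index] == "stenotic"

    def test_linear_taper_is_not_stenotic(self):
        n = 51
        pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, 50, n)])
        frame = s.VesselFrame(
            centerline=s.Centerline(points=pts),
            ring_radius=np.linspace(1.5, 1.2, n),
            phase="diastasis",
        )
        prof = s.compute_stenosis_profile(frame)
        assert np.all(prof.percent_ds <= 20.0)
        assert not prof.stenotic.any()

    def test_all_stenotic_falls_back_with_warning(self):
        n = 31
        pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, 30, n)])
        radii = 1.5 - 1.0 * np.sin(np.linspace(0, np.pi, n))  # everywhere narrowed
        frame = s.VesselFrame(
            centerline=s.Centerline(points=pts), ring_radius=np.abs(radii) + 0.2, phase="diastasis"
        )
        prof = s.compute_stenosis_profile(frame)
        assert np.all(prof.percent_ds >= 0.0)

    @given(st.floats(min_value=5.0, max_value=60.0), st.floats(min_value=5.0, max_value=35.0))
    def test_threshold_monotonicity(self, t1, dt):
        vessel = s.make_stenosis_model(s.PlaqueSpec())
        lo = s.compute_stenosis_profile(vessel.lumen, threshold=t1)
        hi = s.compute_stenosis_profile(vessel.lumen, threshold=min(t1 + dt, 99.0))
        assert hi.stenotic.sum() <= lo.stenotic.sum()


class TestMeshExport:
    @pytest.mark.parametrize("fmt,n_header", [("vtk", 5), ("obj", 1)])
    def test_export_roundtrips_node_count(self, tmp_path, stenotic_mesh, fmt, n_header):
        path = tmp_path / f"mesh.{fmt}"
        s.export_mesh(stenotic_mesh, path, fmt=fmt)
        text = path.read_text().splitlines()
        n_nodes = stenotic_mesh.L * stenotic_mesh.C
        if fmt == "vtk":
            assert f"POINTS {n_nodes} double" in text
        else:
            assert sum(1 for l in text if l.startswith("v ")) == n_nodes
            quads = [l for l in text if l.startswith("f ")]
            assert len(quads) == (stenotic_mesh.L - 1) * stenotic_mesh.C
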