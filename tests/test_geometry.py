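"""Geometric primitives: transforms, mesh proximity, facets, fits."""

import numpy as np
import pytest
import trimesh.creation as tc
from hypothesis import given, settings, strategies as st

from vertmech.geometry import (DegenerateGeometryError, MeshFormatError,
                               PlanarFacet, RigidTransform, TriangleMesh,
                               facet_overlap_fraction, fit_ellipsoid,
                               fit_sphere, load_mesh, mesh_distance,
                               meshes_intersect)


def box_mesh(center, extents=(1.0, 1.0, 1.0)):
    m = tc.box(extents=extents)
    m.apply_translation(center)
    return TriangleMesh.from_trimesh(m)


unit_vec = st.tuples(*[st.floats(-1, 1) for _ in range(3)]).filter(
    lambda v: np.linalg.norm(v) > 1e-3)


class TestRigidTransform:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(axis=unit_vec, angle=st.floats(-180, 180),
           center=st.tuples(*[st.floats(-10, 10) for _ in range(3)]))
    def test_inverse_composes_to_identity(self, axis, angle, center):
        T = RigidTransform.from_axis_angle(axis, angle, center=center)
        assert (T @ T.inverse()).is_identity()
        assert (T.inverse() @ T).is_identity()

    def test_composition_is_associative(self):
        A = RigidTransform.from_axis_angle([1, 0, 0], 30, center=[1, 2, 3])
        B = RigidTransform.from_axis_angle([0, 1, 1], -70, center=[0, 5, 0])
        C = RigidTransform.from_translation([3, -1, 2])
        p = np.array([[0.5, -2.0, 7.0]])
        np.testing.assert_allclose(((A @ B) @ C).apply(p),
                                   (A @ (B @ C)).apply(p), atol=1e-9)

    def test_rejects_improper_rotation(self):
        R = np.diag([1.0, 1.0, -1.0])  # reflection
        with pytest.raises(Exception):
            RigidTransform(R, np.zeros(3))


class TestLoadMesh:
    def test_cube_roundtrip_binary_and_ascii(self, tmp_path):
        cube = tc.box()
        for kind, name in (("stl", "bin.stl"), ("stl_ascii", "asc.stl")):
            cube.export(tmp_path / name, file_type=kind)
        mb = load_mesh(tmp_path / "bin.stl")
        ma = load_mesh(tmp_path / "asc.stl")
        for m in (mb, ma):
            assert m.n_vertices == 8
            assert m.n_faces == 12
        assert np.allclose(np.sort(mb.vertices, axis=0),
                           np.sort(ma.vertices, axis=0), atol=1e-5)

    def test_synthetic_vertebra_roundtrip(self, generic_vertebra, tmp_path):
        path = tmp_path / "v.stl"
        generic_vertebra.mesh.write_stl(path)
        back = load_mesh(path)
        assert back.n_faces == generic_vertebra.mesh.n_faces
        a = np.sort(np.round(back.vertices, 5).view(float).reshape(-1, 3),
                    axis=0)
        b = np.sort(np.round(generic_vertebra.mesh.vertices, 5), axis=0)
        assert np.allclose(a, b, atol=1e-5)

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.stl"
        bad.write_bytes(b"")
        with pytest.raises(MeshFormatError):
            load_mesh(bad)


class TestMeshesIntersect:
    @pytest.mark.parametrize("center,clearance,expected", [
        ((0.5, 0, 0), 0.0, True),      # overlapping boxes
        ((3.0, 0, 0), 0.0, False),     # disjoint
        ((1.2, 0, 0), 0.3, True),      # 0.2 gap vs 0.3 clearance
        ((1.2, 0, 0), 0.1, False),
    ])
    def test_analytic_box_cases(self, center, clearance, expected):
        a = box_mesh((0, 0, 0))
        b = box_mesh(center)
        assert meshes_intersect(a, b, clearance) is expected
        assert meshes_intersect(b, a, clearance) is expected  # symmetry

    def test_monotone_in_clearance(self):
        a = box_mesh((0, 0, 0))
        b = box_mesh((1.5, 0, 0))   # gap 0.5
        results = [meshes_intersect(a, b, c)
                   for c in (0.0, 0.2, 0.4, 0.6, 1.0)]
        # once true, stays true as clearance grows
        assert results == sorted(results)
        assert results[-1] is True

    def test_crossing_thin_boxes_touch(self):
        a = box_mesh((0, 0, 0), extents=(4, 0.1, 0.1))
        b = box_mesh((0, 0, 0), extents=(0.1, 4, 0.1))
        assert meshes_intersect(a, b)
        assert mesh_distance(a, b) == 0.0

    def test_exact_gap_distance(self):
        a = box_mesh((0, 0, 0))
        b = box_mesh((1.75, 0.0, 0.0))
        assert mesh_distance(a, b) == pytest.approx(0.75, abs=1e-12)


SQUARE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)


class TestFacetOverlap:
    def facet(self, offset=(0, 0, 0), normal=(0, 0, 1), kind="pre"):
        return PlanarFacet(SQUARE + np.asarray(offset, float), normal,
                           kind=kind)

    @pytest.mark.parametrize("offset,expected", [
        ((0, 0, 0), 1.0),          # coincident congruent squares
        ((0.5, 0, 0), 0.5),        # half-offset
        ((2.0, 0, 0), 0.0),        # disjoint
    ])
    def test_analytic_fractions(self, offset, expected):
        fixed = self.facet()
        moving = self.facet(offset, normal=(0, 0, -1))
        ov = facet_overlap_fraction(moving, fixed)
        assert ov.fraction == pytest.approx(expected, abs=1e-12)

    def test_disjoint_is_in_plane_separation(self):
        ov = facet_overlap_fraction(self.facet((2, 0, 0), (0, 0, -1)),
                                    self.facet())
        assert ov.fraction == 0.0
        assert ov.in_plane_separation and not ov.normal_separation

    def test_normal_lift_is_dorsoventral_separation(self):
        ov = facet_overlap_fraction(self.facet((0, 0, 0.5), (0, 0, -1)),
                                    self.facet())
        assert ov.normal_separation

    def test_non_opposed_normals_disengage(self):
        ov = facet_overlap_fraction(self.facet(normal=(0, 0, 1)),
                                    self.facet())
        assert ov.fraction == 0.0 and ov.normal_separation

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(axis=unit_vec, angle=st.floats(-90, 90),
           shift=st.tuples(*[st.floats(-5, 5) for _ in range(3)]))
    def test_invariant_under_shared_rigid_transform(self, axis, angle,
                                                    shift):
        fixed = self.facet()
        moving = self.facet((0.3, 0.2, 0), (0, 0, -1))
        base = facet_overlap_fraction(moving, fixed).fraction
        T = RigidTransform.from_axis_angle(axis, angle, center=shift)
        moved = facet_overlap_fraction(moving.transformed(T),
                                       fixed.transformed(T)).fraction
        assert moved == pytest.approx(base, abs=1e-9)


class TestFitSphere:
    def test_exact_recovery(self, rng):
        u = rng.normal(size=(100, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        s = fit_sphere(np.array([1.0, 2.0, 3.0]) + 5.0 * u)
        np.testing.assert_allclose(s.center, [1, 2, 3], atol=1e-9)
        assert s.radius == pytest.approx(5.0, abs=1e-9)
        assert s.rms < 1e-9

    def test_regular_tetrahedron_in_unit_sphere(self):
        t = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1],
                      [-1, -1, 1]]) / np.sqrt(3)
        assert fit_sphere(t).radius == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery(self, rng):
        u = rng.normal(size=(200, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = np.array([1.0, 2.0, 3.0]) + 5.0 * u \
            + rng.normal(0, 0.01, (200, 3))
        s = fit_sphere(pts)
        assert np.linalg.norm(s.center - [1, 2, 3]) < 0.01

    def test_residual_rigid_invariance(self, rng):
        u = rng.normal(size=(50, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = 2.0 * u + rng.normal(0, 0.05, (50, 3))
        base = fit_sphere(pts).rms
        T = RigidTransform.from_axis_angle([1, 2, 3], 47, center=[5, 5, 5])
        assert fit_sphere(T.apply(pts)).rms == pytest.approx(base,
                                                             abs=1e-9)

    def test_coplanar_points_degenerate(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2,
                               np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)


def ellipsoid_points(rng, semi=(2.0, 1.0, 1.0), center=(0, 0, 0), n=300):
    th = rng.uniform(0, np.pi, n)
    ph = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([semi[0] * np.sin(th) * np.cos(ph),
                           semi[1] * np.sin(th) * np.sin(ph),
                           semi[2] * np.cos(th)])
    return pts + np.asarray(center, float)


class TestFitEllipsoid:
    def test_exact_recovery(self, rng):
        e = fit_ellipsoid(ellipsoid_points(rng, center=(0.3, 0.5, -0.2)))
        np.testing.assert_allclose(e.center, [0.3, 0.5, -0.2], atol=1e-6)
        np.testing.assert_allclose(e.semi_axes, [2, 1, 1], atol=1e-6)

    def test_sphere_gives_equal_axes(self, rng):
        e = fit_ellipsoid(ellipsoid_points(rng, semi=(1.5, 1.5, 1.5)))
        assert np.ptp(e.semi_axes) < 1e-6

    def test_noisy_center(self, rng):
        pts = ellipsoid_points(rng, center=(1, -2, 0.5)) \
            + rng.normal(0, 0.01, (300, 3))
        e = fit_ellipsoid(pts)
        assert np.linalg.norm(e.center - [1, -2, 0.5]) < 0.02

    def test_too_few_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            fit_ellipsoid(np.zeros((5, 3)))
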