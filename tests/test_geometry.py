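"""Mesh construction, face diameters, containment, contact and VTK I/O."""

import numpy as np
import pytest

from bronchoreach.airway_model import AirwayBranch, AirwayTree
from bronchoreach.errors import InvalidConfigError, MeshFormatError
from bronchoreach import geometry as G

from conftest import (MASTER_SEED, brute_force_contact, brute_force_nearest,
                      point_segment_distance_scalar, ray_parity_inside)


def single_branch_tree(diameter=5.0, length=30.0):
    b = AirwayBranch(0, None, np.zeros(3), np.array([0.0, 0.0, length]),
                     diameter, 1.0, 0)
    return AirwayTree([b], 0, "inspiration")


class TestTubeSurface:
    def test_face_count_single_branch(self):
        surf = G.tube_surface(single_branch_tree(), 8)
        assert surf.n_faces == 8 * 2 + 2 * 8  # sides + two cap fans
        assert surf.is_closed()

    def test_side_vertices_on_the_cylinder(self):
        surf = G.tube_surface(single_branch_tree(diameter=5.0), 16)
        ring = surf.vertices[:32]  # two rings, before cap centers
        radial = np.linalg.norm(ring[:, :2], axis=1)
        np.testing.assert_allclose(radial, 2.5, atol=1e-6)

    def test_all_vertices_near_some_branch_axis(self, small_tree):
        surf = G.tube_surface(small_tree, 10)
        max_r = max(b.radius for b in small_tree.branches)
        dist = np.full(len(surf.vertices), np.inf)
        for b in small_tree.branches:
            d = np.array([point_segment_distance_scalar(v, b.start, b.end)
                          for v in surf.vertices])
            dist = np.minimum(dist, d)
        assert (dist <= max_r + 1e-6).all()

    def test_face_attribute_is_generating_diameter(self, small_tree):
        surf = G.tube_surface(small_tree, 8)
        diams = {b.id: b.diameter for b in small_tree.branches}
        expected = np.array([diams[i] for i in surf.face_attrs["branch_id"]])
        np.testing.assert_array_equal(surf.face_attrs[G.DIAMETER_ATTR], expected)

    def test_too_few_segments_rejected(self):
        with pytest.raises(InvalidConfigError):
            G.tube_surface(single_branch_tree(), 4)

    def test_empty_tree_rejected(self):
        with pytest.raises(InvalidConfigError):
            G.tube_surface(AirwayTree([], 0, "inspiration"), 8)


class TestSphereSurface:
    def test_refinement_zero_is_icosahedron(self):
        surf = G.sphere_surface([0, 0, 0], 2.0, refinement=0)
        assert surf.n_faces == 20 and len(surf.vertices) == 12

    def test_vertices_exactly_on_radius(self):
        surf = G.sphere_surface([3, -2, 1], 7.0, refinement=2)
        r = np.linalg.norm(surf.vertices - [3, -2, 1], axis=1)
        np.testing.assert_allclose(r, 3.5, atol=1e-9)

    def test_volume_close_to_analytic(self):
        d = 10.0
        surf = G.sphere_surface([0, 0, 0], d, refinement=3)
        vol = surf.to_trimesh().volume
        assert vol == pytest.approx(np.pi / 6 * d**3, rel=0.01)

    def test_center_shift_is_exact_translation(self):
        shift = np.array([1.5, -2.0, 0.25])
        a = G.sphere_surface([0, 0, 0], 4.0, refinement=1)
        b = G.sphere_surface(shift, 4.0, refinement=1)
        np.testing.assert_array_equal(b.vertices, a.vertices + shift)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(InvalidConfigError):
            G.sphere_surface([0, 0, 0], 0.0)


class TestFaceDiameters:
    @pytest.mark.parametrize("diameter", [0.2, 1.0, 5.0, 20.0])
    def test_cylinder_diameter_recovered_within_2pct(self, diameter):
        surf = G.tube_surface(single_branch_tree(diameter, length=6 * diameter), 24)
        fd = G.face_diameters(surf, cutoff=max(40.0, 3 * diameter))
        side = ~surf.face_attrs[G.CAP_ATTR]
        assert np.isfinite(fd[side]).all()
        np.testing.assert_allclose(fd[side], diameter, rtol=0.02)

    def test_cap_faces_are_missing(self):
        surf = G.tube_surface(single_branch_tree(), 12)
        fd = G.face_diameters(surf)
        assert np.isnan(fd[surf.face_attrs[G.CAP_ATTR]]).all()

    def test_icosphere_diameter_recovered(self):
        d = 8.0
        surf = G.sphere_surface([0, 0, 0], d, refinement=2)
        fd = G.face_diameters(surf)
        np.testing.assert_allclose(fd, d, rtol=0.02)

    def test_missing_when_no_opposing_wall(self):
        # half-cylinder shell: inward rays escape through the open half
        surf = G.tube_surface(single_branch_tree(), 16)
        side = ~surf.face_attrs[G.CAP_ATTR]
        centroids = surf.face_centroids()
        keep = side & (centroids[:, 0] > 0)  # one side wall only
        half = G.TriSurface(surf.vertices, surf.faces[keep])
        fd = G.face_diameters(half)
        assert np.isnan(fd).all()


class TestContainment:
    def test_sphere_center_inside_and_far_point_outside(self):
        surf = G.sphere_surface([1, 2, 3], 6.0, refinement=1)
        res = G.point_in_surface(surf, [[1, 2, 3], [50, 50, 50]])
        assert res.tolist() == [True, False]

    def test_agreement_with_analytic_radius(self):
        center = np.array([1.0, 2.0, 3.0])
        surf = G.sphere_surface(center, 10.0, refinement=4)
        rng = np.random.default_rng(MASTER_SEED)
        pts = rng.uniform(-10, 10, (2000, 3)) + center
        inside = G.point_in_surface(surf, pts)
        analytic = np.linalg.norm(pts - center, axis=1) <= 5.0
        agree = inside == analytic
        assert agree.mean() >= 0.999
        if not agree.all():
            off = np.abs(np.linalg.norm(pts[~agree] - center, axis=1) - 5.0)
            assert (off <= surf.median_edge_length()).all()

    def test_agreement_with_ray_parity_oracle(self):
        # parity needs a closed manifold: a single capped tube qualifies
        surf = G.tube_surface(single_branch_tree(diameter=6.0, length=25.0), 12)
        assert surf.is_closed()
        rng = np.random.default_rng(MASTER_SEED)
        lo = surf.vertices.min(axis=0) - 5
        hi = surf.vertices.max(axis=0) + 5
        pts = rng.uniform(lo, hi, (400, 3))
        winding = G.point_in_surface(surf, pts)
        parity = ray_parity_inside(surf, pts, rng)
        assert (winding == parity).mean() >= 0.999

    def test_open_surface_rejected(self):
        surf = G.sphere_surface([0, 0, 0], 4.0, refinement=1)
        opened = G.TriSurface(surf.vertices, surf.faces[1:])
        with pytest.raises(MeshFormatError):
            G.point_in_surface(opened, [[0, 0, 0]])


class TestLesionAirwayContact:
    def test_lesion_on_trachea_axis_touches_trachea(self, default_tree):
        trachea = default_tree.branches[0]
        center = (trachea.start + trachea.end) / 2
        touched = G.lesion_airway_contact(center, trachea.diameter + 2, default_tree)
        assert len(touched) > 0
        assert np.any(np.abs(touched - trachea.diameter) / trachea.diameter < 0.02)

    def test_far_lesion_touches_nothing(self, small_tree):
        touched = G.lesion_airway_contact([1000.0, 1000.0, 1000.0], 10.0, small_tree)
        assert len(touched) == 0

    def test_fast_path_equals_brute_force(self, small_tree):
        rng = np.random.default_rng(MASTER_SEED)
        lo, hi = small_tree.lung_region.bounding_box()
        for _ in range(50):
            center = rng.uniform(lo, hi)
            d = rng.uniform(1, 30)
            fast = G.lesion_airway_contact(center, d, small_tree)
            oracle = brute_force_contact(center, d, small_tree)
            np.testing.assert_allclose(fast, oracle)

    def test_contact_set_monotone_in_lesion_diameter(self, small_tree):
        rng = np.random.default_rng(MASTER_SEED)
        lo, hi = small_tree.lung_region.bounding_box()
        for _ in range(20):
            center = rng.uniform(lo, hi)
            small = G.lesion_airway_contact(center, 8.0, small_tree)
            large = G.lesion_airway_contact(center, 20.0, small_tree)
            assert set(small).issubset(set(large))

    def test_mesh_path_matches_vertex_scan(self, small_tree):
        surf = G.tube_surface(small_tree, 10, axial_step=2.0)
        fdm = surf.face_attrs[G.DIAMETER_ATTR].copy()
        fdm[surf.face_attrs[G.CAP_ATTR]] = np.nan
        rng = np.random.default_rng(MASTER_SEED)
        lo, hi = small_tree.lung_region.bounding_box()
        for _ in range(20):
            center = rng.uniform(lo, hi)
            d = rng.uniform(2, 25)
            got = G.lesion_airway_contact(center, d, (surf, fdm))
            # oracle: all-vertex + centroid distance scan over the same mesh
            r = d / 2
            vhit = np.linalg.norm(surf.vertices - center, axis=1) <= r
            fhit = vhit[surf.faces].any(axis=1)
            fhit |= np.linalg.norm(surf.face_centroids() - center, axis=1) <= r
            expected = np.unique(fdm[fhit & np.isfinite(fdm)])
            np.testing.assert_allclose(got, expected)

    def test_nonpositive_lesion_rejected(self, small_tree):
        with pytest.raises(InvalidConfigError):
            G.lesion_airway_contact([0, 0, 0], -1.0, small_tree)


class TestNearestAirwayDistance:
    def test_zero_inside_trachea(self, default_tree):
        trachea = default_tree.branches[0]
        center = (trachea.start + trachea.end) / 2
        assert G.nearest_airway_distance(center, default_tree, 1.0) == 0.0

    def test_infinite_when_no_airway_qualifies(self, default_tree):
        trachea = default_tree.branches[0]
        assert np.isinf(G.nearest_airway_distance(
            [0, 0, 0], default_tree, trachea.diameter + 1.0))

    def test_matches_brute_force_scan(self, small_tree):
        rng = np.random.default_rng(MASTER_SEED)
        lo, hi = small_tree.lung_region.bounding_box()
        for _ in range(100):
            p = rng.uniform(lo, hi)
            min_d = rng.uniform(0, 12)
            got = G.nearest_airway_distance(p, small_tree, min_d)
            expected = brute_force_nearest(p, small_tree, min_d)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_non_decreasing_in_min_diameter(self, small_tree):
        rng = np.random.default_rng(MASTER_SEED)
        lo, hi = small_tree.lung_region.bounding_box()
        for _ in range(20):
            p = rng.uniform(lo, hi)
            dists = [G.nearest_airway_distance(p, small_tree, m)
                     for m in (0.5, 1.0, 2.0, 4.0, 8.0)]
            assert all(b >= a - 1e-12 for a, b in zip(dists, dists[1:]))


class TestVtkIO:
    def test_icosahedron_round_trip(self, tmp_path):
        surf = G.sphere_surface([0, 0, 0], 2.0, refinement=0)
        path = tmp_path / "ico.vtk"
        G.write_vtk(surf, path, scalar_attr=None)
        back = G.read_vtk(path)
        assert len(back.vertices) == 12 and back.n_faces == 20
        np.testing.assert_allclose(back.vertices, surf.vertices, atol=1e-6)
        np.testing.assert_array_equal(back.faces, surf.faces)

    def test_face_scalar_round_trip_with_nan(self, small_tree, tmp_path):
        surf = G.tube_surface(small_tree, 8)
        fdm = surf.face_attrs[G.DIAMETER_ATTR].copy()
        fdm[::7] = np.nan
        surf.face_attrs[G.DIAMETER_ATTR] = fdm
        path = tmp_path / "tree.vtk"
        G.write_vtk(surf, path)
        back = G.read_vtk(path)
        np.testing.assert_allclose(back.face_attrs[G.DIAMETER_ATTR], fdm,
                                   atol=1e-6, equal_nan=True)

    def test_quad_polygon_rejected(self, tmp_path):
        path = tmp_path / "quad.vtk"
        path.write_text("\n".join([
            "# vtk DataFile Version 3.0", "quad", "ASCII", "DATASET POLYDATA",
            "POINTS 4 float", "0 0 0", "1 0 0", "1 1 0", "0 1 0",
            "POLYGONS 1 5", "4 0 1 2 3", ""]))
        with pytest.raises(MeshFormatError, match="non-triangle"):
            G.read_vtk(path)

    def test_malformed_points_reports_line(self, tmp_path):
        path = tmp_path / "bad.vtk"
        path.write_text("\n".join([
            "# vtk DataFile Version 3.0", "bad", "ASCII", "DATASET POLYDATA",
            "POINTS 2 float", "0 0 0", "zero zero zero", ""]))
        with pytest.raises(MeshFormatError, match=":7"):
            G.read_vtk(path)
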