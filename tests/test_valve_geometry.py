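"""Parametric leaflet construction, assembly, placement and orifice projection."""

import numpy as np
import pytest

from valvemetrics.valve_geometry import (RigidTransform, SurfaceMesh, ValveDesign,
                                         assemble_valve, build_leaflet,
                                         default_design, goa_from_free_edges,
                                         place_valve, projected_polygon_area)


def _slab_design(r=8.0, gap=6.0, thickness=0.4):
    """Planar D-shaped leaflet: semicircular free edge lofted to a straight
    directrix offset below it, all in the z=0 plane."""
    th = np.linspace(0, np.pi, 9)
    free_edge = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(9)])
    directrix = np.column_stack([np.linspace(r, -r, 9), np.full(9, -gap), np.zeros(9)])
    return ValveDesign(nominal_diameter=2.1 * (r + gap), leaflet_thickness=thickness,
                       free_edge_ctrl=free_edge, directrix_ctrl=directrix,
                       profile_height=1.0)


class TestBuildLeaflet:
    def test_watertight_and_consistent(self, leaflet_mesh):
        tm = leaflet_mesh.to_trimesh()
        assert tm.is_watertight
        assert tm.is_winding_consistent

    def test_flat_slab_volume_oracle(self):
        """A planar semicircular free edge lofted to a straight directrix
        gives a flat slab: volume = planar area x thickness."""
        r, gap, t = 8.0, 6.0, 0.4
        mesh = build_leaflet(_slab_design(r, gap, t), resolution=(48, 16))
        # swept planar region: half disc (the spline tracks the circle
        # closely at 9 control points) plus the rectangular strip
        area = np.pi * r**2 / 2 + 2 * r * gap
        assert mesh.volume() == pytest.approx(area * t, rel=1e-2)

    def test_volume_vanishes_with_thickness(self):
        v_thick = build_leaflet(_slab_design(thickness=0.4), resolution=(16, 8)).volume()
        v_thin = build_leaflet(_slab_design(thickness=0.004), resolution=(16, 8)).volume()
        assert v_thin == pytest.approx(v_thick / 100, rel=1e-6)

    def test_shell_volume_tracks_midsurface_area(self):
        """For gentle curvature the shell volume is mid-surface area x thickness.

        A thin shell is used so the rim strip contributes negligibly to the
        total surface area and area/2 approximates the mid-surface."""
        d = _slab_design(thickness=0.04)
        mesh = build_leaflet(d, resolution=(32, 16))
        mid_area = mesh.area() / 2
        assert mesh.volume() == pytest.approx(mid_area * d.leaflet_thickness, rel=2e-2)

    def test_default_design_fits_envelope(self, leaflet_mesh):
        assert np.ptp(leaflet_mesh.vertices, axis=0).max() <= 25.0 * 1.05

    def test_excessive_thickness_raises(self):
        # arched free edge over a straight directrix: tightly curved loft
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        free_edge = np.column_stack([x, np.zeros(5), [0.0, 1.8, 2.4, 1.8, 0.0]])
        directrix = np.column_stack([x, np.full(5, -4.0), np.zeros(5)])
        curved = ValveDesign(nominal_diameter=14.0, leaflet_thickness=5.0,
                             free_edge_ctrl=free_edge, directrix_ctrl=directrix,
                             profile_height=3.0)
        with pytest.raises(ValueError, match="thickness"):
            build_leaflet(curved, resolution=(24, 12))

    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            build_leaflet(default_design(), resolution=(4, 4))


class TestAssembleValve:
    def test_three_fold_copy_counts(self, leaflet_mesh):
        valve = assemble_valve(leaflet_mesh)
        assert len(valve.vertices) == 3 * len(leaflet_mesh.vertices)
        assert len(valve.triangles) == 3 * len(leaflet_mesh.triangles)
        assert set(valve.face_labels) == {"LCL", "RCL", "NCL"}

    def test_rotation_symmetry(self, leaflet_mesh):
        valve = assemble_valve(leaflet_mesh)
        a = np.deg2rad(120)
        Rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        rotated = valve.vertices @ Rz.T
        # rotating by 120 deg permutes the three leaflet blocks
        n = len(leaflet_mesh.vertices)
        np.testing.assert_allclose(rotated[:n], valve.vertices[n:2 * n], atol=1e-9)
        np.testing.assert_allclose(rotated[2 * n:], valve.vertices[:n], atol=1e-9)

    def test_equal_centroid_distances(self, leaflet_mesh):
        valve = assemble_valve(leaflet_mesh)
        n = len(leaflet_mesh.vertices)
        cents = [valve.vertices[i * n:(i + 1) * n].mean(axis=0) for i in range(3)]
        d = [np.linalg.norm(cents[i] - cents[(i + 1) % 3]) for i in range(3)]
        assert d[0] == pytest.approx(d[1], rel=1e-9)
        assert d[1] == pytest.approx(d[2], rel=1e-9)


class TestPlaceValve:
    def test_identity(self, leaflet_mesh):
        placed = place_valve(leaflet_mesh, RigidTransform.identity())
        np.testing.assert_array_equal(placed.vertices, leaflet_mesh.vertices)

    def test_translation_preserves_edge_lengths(self, leaflet_mesh):
        tr = RigidTransform(np.eye(3), np.array([5.0, -3.0, 12.0]))
        placed = place_valve(leaflet_mesh, tr)
        e0 = leaflet_mesh.vertices[leaflet_mesh.triangles]
        e1 = placed.vertices[placed.triangles]
        np.testing.assert_allclose(
            np.linalg.norm(e0[:, 1] - e0[:, 0], axis=1),
            np.linalg.norm(e1[:, 1] - e1[:, 0], axis=1), rtol=1e-9)

    def test_composition_matches_matrix_product(self, leaflet_mesh):
        rng = np.random.default_rng(3)
        from scipy.spatial.transform import Rotation
        t1 = RigidTransform(Rotation.random(random_state=1).as_matrix(), rng.normal(size=3))
        t2 = RigidTransform(Rotation.random(random_state=2).as_matrix(), rng.normal(size=3))
        seq = place_valve(place_valve(leaflet_mesh, t1), t2)
        combo = place_valve(leaflet_mesh, t2.compose(t1))
        np.testing.assert_allclose(seq.vertices, combo.vertices, atol=1e-9)

    def test_improper_rotation_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])  # reflection
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))


def _circle_arcs(radius_mm=10.0, n_per_arc=100, z=5.0):
    arcs = []
    for j in range(3):
        th = np.deg2rad(np.linspace(120 * j, 120 * (j + 1), n_per_arc))
        arcs.append(np.column_stack([radius_mm * np.cos(th), radius_mm * np.sin(th),
                                     np.full(th.size, z)]))
    return arcs


class TestGOA:
    def test_projected_circle_area(self):
        arcs = _circle_arcs(radius_mm=10.0)  # 1 cm radius
        assert goa_from_free_edges(arcs) == pytest.approx(np.pi, rel=1e-3)

    def test_tilted_square_projection_factor(self):
        theta = np.deg2rad(30)
        sq = np.array([[0, 0, 0], [10, 0, 0], [10, 10 * np.cos(theta), 10 * np.sin(theta)],
                       [0, 10 * np.cos(theta), 10 * np.sin(theta)]], dtype=float)
        area = projected_polygon_area(sq, np.array([0.0, 0.0, 1.0]))
        assert area == pytest.approx(100 * np.cos(theta), rel=1e-12)

    def test_rotation_and_translation_invariance(self):
        arcs = _circle_arcs()
        base = goa_from_free_edges(arcs)
        a = np.deg2rad(77)
        Rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        moved = [arc @ Rz.T + np.array([3.0, -2.0, 7.0]) for arc in arcs]
        assert goa_from_free_edges(moved) == pytest.approx(base, rel=1e-12)

    def test_three_lobed_curve_vs_rasterization_oracle(self):
        # closed trefoil-modulated circuit split into three polylines
        th = np.linspace(0, 2 * np.pi, 301)
        r = 10.0 + 2.0 * np.cos(3 * th)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(th.size)])
        arcs = [pts[0:101], pts[100:201], pts[200:301]]
        area = goa_from_free_edges(arcs)
        from shapely.geometry import Polygon
        oracle = Polygon(pts[:, :2]).area / 100.0  # mm^2 -> cm^2
        assert area == pytest.approx(oracle, rel=1e-3)

    def test_degenerate_circuit_zero(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)])
        # out-and-back collinear circuit closed by a degenerate stub
        arcs = [line, line[::-1], np.zeros((2, 3))]
        assert goa_from_free_edges(arcs) == 0.0

    def test_unjoined_polylines_rejected(self):
        arcs = _circle_arcs()
        arcs[1] = arcs[1] + np.array([5.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="join"):
            goa_from_free_edges(arcs)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            goa_from_free_edges(_circle_arcs(), axis=np.array([0.0, 0.0, 2.0]))
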