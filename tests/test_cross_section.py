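import math

import numpy as np
import pytest
import trimesh
from shapely.geometry import Polygon

from platemetry.cross_section import (
    SectionError,
    SectionPlane,
    loop_area_centroid,
    select_section_loop,
    slice_with_plane,
    width_thickness,
)


def _plane(origin=(0, 0, 0), normal=(0, 0, 1), u=(1, 0, 0), v=(0, 1, 0)):
    return SectionPlane(origin=origin, normal=normal, u=u, v=v)


def _chain_components(segments, tol=1e-6):
    """Independent oracle: count connected components of the segment graph."""
    pts = segments.reshape(-1, 3)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    parent = list(range(len(pts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = list(tree.query_pairs(tol)) + [(2 * i, 2 * i + 1) for i in range(len(segments))]
    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return len({find(i) for i in range(len(pts))})


class TestSlice:
    def test_cylinder_midheight_circle(self):
        cyl = trimesh.creation.cylinder(radius=5, height=20, sections=256)
        loops = slice_with_plane(cyl, _plane())
        assert len(loops) == 1
        area, _ = loop_area_centroid(_plane().to_2d(loops[0]))
        assert area == pytest.approx(math.pi * 25, rel=0.005)

    def test_plane_outside_mesh_empty(self):
        cyl = trimesh.creation.cylinder(radius=5, height=20)
        assert slice_with_plane(cyl, _plane(origin=(0, 0, 30))) == []

    def test_two_disjoint_cylinders_two_loops(self):
        a = trimesh.creation.cylinder(radius=3, height=10, sections=64)
        b = a.copy()
        b.apply_translation([20, 0, 0])
        both = trimesh.util.concatenate([a, b])
        loops = slice_with_plane(both, _plane())
        assert len(loops) == 2
        # oracle: connected components of the raw intersection segments
        segs = trimesh.intersections.mesh_plane(
            both, plane_normal=[0, 0, 1.0], plane_origin=[0, 0, 0.0]
        )
        assert _chain_components(segs) == 2

    def test_watertight_mesh_gives_closed_loops_only(self, default_phantom, caplog):
        mesh, _, _ = default_phantom
        plane = _plane(origin=(0, 0, -10), normal=(0, 0, -1), u=(0, 1, 0), v=(1, 0, 0))
        with caplog.at_level("WARNING", logger="platemetry"):
            loops = slice_with_plane(mesh, plane)
        assert loops
        assert "discarding" not in caplog.text


class TestSelect:
    def test_nearest_centroid_wins(self):
        near = np.array([[2, 0, 0], [3, 1, 0], [4, 0, 0], [3, -1, 0]], dtype=float)
        far = near + np.array([30.0, 0, 0])
        chosen = select_section_loop([far, near], anchor=np.zeros(3), min_area=0.0)
        assert np.array_equal(chosen, near)

    def test_empty_raises(self):
        with pytest.raises(SectionError):
            select_section_loop([], anchor=np.zeros(3))

    def test_equidistant_tie_is_deterministic(self):
        small = np.array([[5, 1, 0], [5, -1, 0], [6, 0, 0]], dtype=float)
        big = -np.array([[4, 2, 0], [4, -2, 0], [7, 0, 0], [7, 0.1, 0]], dtype=float)
        big = big * np.array([1, 1, 1.0])
        # mirror so both centroids are equidistant from the origin anchor
        d_small = np.linalg.norm(small.mean(axis=0))
        big = big / np.linalg.norm(big.mean(axis=0)) * d_small
        for _ in range(3):
            chosen = select_section_loop([big, small], anchor=np.zeros(3), min_area=0.0)
            assert np.array_equal(chosen, select_section_loop([small, big], np.zeros(3), min_area=0.0))

    def test_sliver_loops_ignored(self):
        sliver = np.array([[0.1, 0, 0], [0.2, 1e-6, 0], [0.3, 0, 0]], dtype=float)
        ring = np.array([[4, 2, 0], [6, 2, 0], [6, -2, 0], [4, -2, 0]], dtype=float)
        chosen = select_section_loop([sliver, ring], anchor=np.zeros(3))
        assert np.array_equal(chosen, ring)


class TestAreaCentroid:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        area, centroid = loop_area_centroid(square)
        assert area == pytest.approx(1.0)
        assert np.allclose(centroid, [0.5, 0.5])

    def test_regular_polygon_closed_form(self):
        n, r = 360, 5.0
        theta = 2 * math.pi * np.arange(n) / n
        poly = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        area, centroid = loop_area_centroid(poly)
        assert area == pytest.approx((n / 2) * r * r * math.sin(2 * math.pi / n), rel=1e-12)
        assert np.allclose(centroid, 0.0, atol=1e-9)

    def test_orientation_invariant(self):
        poly = np.array([[0, 0], [4, 1], [5, 4], [1, 3]], dtype=float)
        a1, c1 = loop_area_centroid(poly)
        a2, c2 = loop_area_centroid(poly[::-1])
        assert a1 == pytest.approx(a2)
        assert np.allclose(c1, c2)

    def test_matches_shapely(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            theta = np.sort(rng.uniform(0, 2 * math.pi, 12))
            radius = rng.uniform(2, 6, 12)
            poly = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
            area, centroid = loop_area_centroid(poly)
            ref = Polygon(poly)
            assert area == pytest.approx(ref.area, rel=1e-12)
            assert np.allclose(centroid, [ref.centroid.x, ref.centroid.y], atol=1e-9)

    def test_degenerate_rejected(self):
        line = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        with pytest.raises(SectionError):
            loop_area_centroid(line)


def _brute_force_extent(loop, centroid, direction):
    """Exhaustive segment-line intersection oracle for width/thickness."""
    d = np.asarray(direction, dtype=float)
    n = np.array([-d[1], d[0]])
    ts = []
    for i in range(len(loop)):
        a, b = loop[i], loop[(i + 1) % len(loop)]
        sa, sb = (a - centroid) @ n, (b - centroid) @ n
        if (sa > 0) != (sb > 0):
            crossing = a + sa / (sa - sb) * (b - a)
            ts.append((crossing - centroid) @ d)
    return max(ts) - min(ts)


class TestWidthThickness:
    def test_circle(self):
        theta = 2 * math.pi * np.arange(720) / 720
        circle = np.column_stack([5 * np.cos(theta), 5 * np.sin(theta)])
        w, t, _, _ = width_thickness(circle, _plane())
        assert w == pytest.approx(10.0, rel=0.005)
        assert t == pytest.approx(10.0, rel=0.005)

    def test_ellipse(self):
        theta = 2 * math.pi * np.arange(720) / 720
        ellipse = np.column_stack([6 * np.cos(theta), 2 * np.sin(theta)])
        w, t, w_pts, t_pts = width_thickness(ellipse, _plane())
        assert w == pytest.approx(12.0, rel=0.005)
        assert t == pytest.approx(4.0, rel=0.005)
        assert np.linalg.norm(w_pts[0] - w_pts[1]) == pytest.approx(w)

    def test_concave_c_shape_matches_brute_force(self):
        outer = [[0, 0], [10, 0], [10, 2], [3, 2], [3, 8], [10, 8], [10, 10], [0, 10]]
        loop = np.array(outer, dtype=float)
        _, centroid = loop_area_centroid(loop)
        w, t, _, _ = width_thickness(loop, _plane())
        assert w == pytest.approx(_brute_force_extent(loop, centroid, [1, 0]))
        assert t == pytest.approx(_brute_force_extent(loop, centroid, [0, 1]))

    def test_traversal_direction_irrelevant(self):
        theta = 2 * math.pi * np.arange(90) / 90
        ellipse = np.column_stack([6 * np.cos(theta), 2 * np.sin(theta)])
        w1, t1, _, _ = width_thickness(ellipse, _plane())
        w2, t2, _, _ = width_thickness(ellipse[::-1], _plane())
        assert w1 == pytest.approx(w2)
        assert t1 == pytest.approx(t2)


class TestRigidInvariance:
    def test_measures_invariant_under_joint_transform(self):
        cyl = trimesh.creation.cylinder(radius=4, height=16, sections=128)
        plane = _plane()
        loops = slice_with_plane(cyl, plane)
        uv = plane.to_2d(select_section_loop(loops, np.zeros(3)))
        area, _ = loop_area_centroid(uv)
        w, t, _, _ = width_thickness(uv, plane)

        matrix = trimesh.transformations.euler_matrix(0.4, -0.9, 1.7)
        matrix[:3, 3] = [12, -5, 9]
        moved = cyl.copy()
        moved.apply_transform(matrix)
        R, tr = matrix[:3, :3], matrix[:3, 3]
        plane2 = SectionPlane(origin=tr, normal=R @ [0, 0, 1.0], u=R @ [1.0, 0, 0], v=R @ [0, 1.0, 0])
        loops2 = slice_with_plane(moved, plane2)
        uv2 = plane2.to_2d(select_section_loop(loops2, tr))
        area2, _ = loop_area_centroid(uv2)
        w2, t2, _, _ = width_thickness(uv2, plane2)
        assert area2 == pytest.approx(area, abs=1e-6)
        assert w2 == pytest.approx(w, abs=1e-6)
        assert t2 == pytest.approx(t, abs=1e-6)
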