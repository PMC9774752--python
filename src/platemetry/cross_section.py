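"""Planar cross-sections of the appliance mesh.

A section plane carries its own in-plane axes: ``u`` is the width direction
(mediolateral for effective sections) and ``v`` the thickness direction.
Slicing the triangle mesh yields unordered intersection segments; these are
chained by shared endpoints into closed loops, open chains are closed when
the remaining gap is small (non-watertight scan meshes) and discarded
otherwise.  One loop per section is attributed to the extension by proximity
to an anchor point, then measured: unsigned shoelace area, first-moment
centroid, and the width/thickness as the extreme boundary intersections of
the centroid lines along ``u`` and ``v``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.validation import make_valid

log = logging.getLogger("platemetry")


class SectionError(ValueError):
    """Raised when a required section cannot be produced or measured."""


@dataclasses.dataclass
class SectionPlane:
    """A cutting plane with oriented in-plane axes (all unit, orthogonal)."""

    origin: np.ndarray
    normal: np.ndarray
    u: np.ndarray  # width direction
    v: np.ndarray  # thickness direction

    def __post_init__(self):
        for name in ("origin", "normal", "u", "v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for a, b in (("normal", "u"), ("normal", "v"), ("u", "v")):
            if abs(getattr(self, a) @ getattr(self, b)) > 1e-9:
                raise ValueError(f"section plane axes {a} and {b} are not orthogonal")

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points, dtype=float) - self.origin
        return np.column_stack([rel @ self.u, rel @ self.v])

    def to_3d(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(uv)
        return self.origin + np.outer(uv[:, 0], self.u) + np.outer(uv[:, 1], self.v)


@dataclasses.dataclass
class SectionResult:
    """One measured cross-section of the extension."""

    loop: np.ndarray  # (n, 2) closed polygon in (u, v) plane coords, first != last
    centroid: np.ndarray  # 3D, mm
    area: float  # mm^2
    width: float  # mm
    thickness: float  # mm
    width_endpoints: np.ndarray  # (2, 3)
    thickness_endpoints: np.ndarray  # (2, 3)
    offset: float  # mm along the frame normal (effective) or sagittal axis (cleft)
    plane: SectionPlane = None


def slice_with_plane(
    mesh: trimesh.Trimesh,
    plane: SectionPlane,
    chain_tol: float = 1e-6,
    close_gap: float = 0.5,
) -> list[np.ndarray]:
    """Intersect the mesh with a plane; return closed loops as (n, 3) arrays.

    Triangle-plane intersection segments are chained by shared endpoints
    (tolerance ``chain_tol``); open chains whose end gap is below
    ``close_gap`` are closed by joining their endpoints, longer open chains
    are discarded with a warning.  An empty list is a valid result (plane
    misses the mesh).
    """
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=plane.normal, plane_origin=plane.origin
    )
    if len(segments) == 0:
        return []
    # merge endpoints within chain_tol (union-find over close pairs; plain
    # grid rounding would split coincident points straddling a cell border)
    pts = segments.reshape(-1, 3)
    tree = cKDTree(pts)
    parent = np.arange(len(pts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in sorted(map(tuple, tree.query_pairs(chain_tol))):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(pts))])
    unique_roots, inverse = np.unique(roots, return_inverse=True)
    coords = pts[unique_roots]
    edge = inverse.reshape(-1, 2)
    # drop zero-length segments
    edge = edge[edge[:, 0] != edge[:, 1]]
    if len(edge) == 0:
        return []
    edge = np.unique(np.sort(edge, axis=1), axis=0)

    # adjacency map node -> neighbours
    neighbours: dict[int, list[int]] = {}
    for a, b in edge:
        neighbours.setdefault(int(a), []).append(int(b))
        neighbours.setdefault(int(b), []).append(int(a))

    visited_edges = set()
    loops: list[np.ndarray] = []
    for start in sorted(neighbours):
        for nxt in sorted(neighbours[start]):
            if (min(start, nxt), max(start, nxt)) in visited_edges:
                continue
            chain = [start, nxt]
            visited_edges.add((min(start, nxt), max(start, nxt)))
            while True:
                here, prev = chain[-1], chain[-2]
                step = None
                for cand in sorted(neighbours[here]):
                    e = (min(here, cand), max(here, cand))
                    if cand != prev and e not in visited_edges:
                        step = cand
                        visited_edges.add(e)
                        break
                if step is None:
                    break
                chain.append(step)
                if step == chain[0]:
                    break
            closed = chain[0] == chain[-1]
            nodes = chain[:-1] if closed else chain
            points = coords[nodes]
            if not closed:
                gap = np.linalg.norm(coords[chain[0]] - coords[chain[-1]])
                if gap >= close_gap:
                    log.warning(
                        "slice_with_plane: discarding open chain of %d points "
                        "(gap %.3f mm)", len(chain), gap,
                    )
                    continue
                log.debug("slice_with_plane: closing chain gap of %.4f mm", gap)
            if len(points) >= 3:
                loops.append(points)
    return loops


def select_section_loop(
    loops: list[np.ndarray], anchor: np.ndarray, min_area: float = 0.5
) -> np.ndarray:
    """The loop whose centroid lies nearest ``anchor``.

    Degenerate sliver loops (area below ``min_area`` mm^2, e.g. where a
    section plane grazes the part tangentially) are ignored unless nothing
    else exists.  Ties are broken by smaller enclosed area, then by
    lexicographic centroid, so repeated runs pick the same loop.
    """
    if not loops:
        raise SectionError("no section loop available at this plane")
    anchor = np.asarray(anchor, dtype=float)
    keys = []
    for i, loop in enumerate(loops):
        centroid = loop.mean(axis=0)
        dist = np.linalg.norm(centroid - anchor)
        # unsigned area via cross products around the vertex mean (3D shoelace)
        rel = loop - centroid
        area = 0.5 * np.linalg.norm(np.cross(rel, np.roll(rel, -1, axis=0)).sum(axis=0))
        keys.append((round(dist, 9), round(area, 9), tuple(np.round(centroid, 9)), i))
    substantial = [k for k in keys if k[1] >= min_area]
    keys = substantial if substantial else keys
    keys.sort()
    return loops[keys[0][3]]


def loop_area_centroid(loop_uv: np.ndarray) -> tuple[float, np.ndarray]:
    """Unsigned shoelace area and first-moment centroid of a planar polygon.

    ``loop_uv`` is an (n, 2) array of vertices (implicitly closed).  The
    centroid is the area centroid (first moment over area), independent of
    traversal direction.  Degenerate loops (area below 1e-9) are rejected.
    """
    loop_uv = np.asarray(loop_uv, dtype=float)
    if loop_uv.ndim != 2 or loop_uv.shape[1] != 2 or len(loop_uv) < 3:
        raise SectionError("loop must be an (n>=3, 2) polygon")
    if np.allclose(loop_uv[0], loop_uv[-1]):
        loop_uv = loop_uv[:-1]
    x, y = loop_uv[:, 0], loop_uv[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    signed_area = 0.5 * cross.sum()
    if abs(signed_area) < 1e-9:
        raise SectionError("degenerate loop: area below 1e-9 mm^2")
    cx = ((x + xn) * cross).sum() / (6.0 * signed_area)
    cy = ((y + yn) * cross).sum() / (6.0 * signed_area)
    return abs(signed_area), np.array([cx, cy])


def _line_crossings(loop_uv: np.ndarray, point: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Parameters t of all intersections of line point + t*direction with the polygon boundary."""
    a = loop_uv
    b = np.roll(loop_uv, -1, axis=0)
    d = np.asarray(direction, dtype=float)
    n = np.array([-d[1], d[0]])  # normal of the cutting line
    sa = (a - point) @ n
    sb = (b - point) @ n
    hit = (sa > 0) != (sb > 0)
    ts = []
    for i in np.nonzero(hit)[0]:
        frac = sa[i] / (sa[i] - sb[i])
        crossing = a[i] + frac * (b[i] - a[i])
        ts.append((crossing - point) @ d)
    return np.sort(np.asarray(ts))


def width_thickness(loop_uv: np.ndarray, plane: SectionPlane) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Width and thickness of a section loop through its centroid.

    Width is the distance between the two extreme intersections of the line
    through the area centroid along ``u`` with the loop boundary; thickness
    likewise along ``v``.  For concave loops yielding more than two
    intersections, the farthest pair is used.  Returns
    ``(W, T, width_endpoints_3d, thickness_endpoints_3d)``.
    """
    _, centroid = loop_area_centroid(loop_uv)
    out = []
    for direction in (np.array([1.0, 0.0]), np.array([0.0, 1.0])):
        ts = _line_crossings(loop_uv, centroid, direction)
        if len(ts) < 2:
            raise SectionError(
                "line through the section centroid misses the loop boundary"
            )
        lo, hi = ts[0], ts[-1]
        endpoints = plane.to_3d(
            np.stack([centroid + lo * direction, centroid + hi * direction])
        )
        out.append((float(hi - lo), endpoints))
    (width, w_pts), (thickness, t_pts) = out
    return width, thickness, w_pts, t_pts


def clean_loop(loop_uv: np.ndarray) -> np.ndarray:
    """Repair a self-intersecting polygon, keeping the largest valid part."""
    poly = Polygon(loop_uv)
    if poly.is_valid:
        return loop_uv
    fixed = make_valid(poly)
    best = None
    for geom in getattr(fixed, "geoms", [fixed]):
        if geom.geom_type == "Polygon" and (best is None or geom.area > best.area):
            best = geom
    if best is None:
        raise SectionError("section loop could not be repaired into a polygon")
    return np.asarray(best.exterior.coords)[:-1]


def measure_section(
    mesh: trimesh.Trimesh,
    plane: SectionPlane,
    anchor: np.ndarray,
    offset: float,
    chain_tol: float = 1e-6,
    close_gap: float = 0.5,
) -> SectionResult:
    """Slice, attribute and fully measure one cross-section."""
    loops = slice_with_plane(mesh, plane, chain_tol=chain_tol, close_gap=close_gap)
    if not loops:
        raise SectionError(f"no intersection loop at offset {offset:.3f} mm")
    loop3d = select_section_loop(loops, anchor)
    loop_uv = clean_loop(plane.to_2d(loop3d))
    area, centroid_uv = loop_area_centroid(loop_uv)
    width, thickness, w_pts, t_pts = width_thickness(loop_uv, plane)
    centroid = plane.to_3d(centroid_uv)[0]
    return SectionResult(
        loop=loop_uv,
        centroid=centroid,
        area=area,
        width=width,
        thickness=thickness,
        width_endpoints=w_pts,
        thickness_endpoints=t_pts,
        offset=offset,
        plane=plane,
    )
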