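"""Quadric edge-collapse decimation, batched and fully deterministic.

Classic quadric error metrics: every vertex accumulates the squared-distance
quadric of its incident face planes (area weighted); collapsing edge (a, b)
moves both endpoints to the position minimising the summed quadric, at a cost
equal to the residual.  Boundary edges contribute a heavily weighted
perpendicular constraint plane so open rims are preserved.

Instead of a serial greedy heap, collapses are applied in passes: all edge
costs are evaluated vectorised, edges are sorted by (cost, index) and a
vertex-disjoint prefix is collapsed simultaneously.  The pass structure keeps
the procedure deterministic for byte-identical input (stable sorts, explicit
tie-breaks) while staying fast in pure numpy.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

_BOUNDARY_WEIGHT = 1e3


def _face_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex 4x4 error quadrics from incident face planes."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    normal = np.cross(v1 - v0, v2 - v0)
    double_area = np.linalg.norm(normal, axis=1)
    keep = double_area > 1e-14
    unit = np.zeros_like(normal)
    unit[keep] = normal[keep] / double_area[keep, None]
    d = -np.einsum("ij,ij->i", unit, v0)
    plane = np.column_stack([unit, d])  # (F, 4)
    # weight by face area so large faces dominate
    kp = plane[:, :, None] * plane[:, None, :] * (0.5 * double_area)[:, None, None]

    quadrics = np.zeros((len(vertices), 4, 4))
    for corner in range(3):
        np.add.at(quadrics, faces[:, corner], kp)

    # boundary constraint: for edges used by exactly one face, add the plane
    # through the edge perpendicular to that face, strongly weighted
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edge_face_normal = np.concatenate([unit, unit, unit])
    edges_sorted = np.sort(edges, axis=1)
    order = np.lexsort((edges_sorted[:, 1], edges_sorted[:, 0]))
    es = edges_sorted[order]
    first = np.ones(len(es), dtype=bool)
    first[1:] = np.any(es[1:] != es[:-1], axis=1)
    # count occurrences per unique edge
    group_id = np.cumsum(first) - 1
    counts = np.bincount(group_id)
    boundary_rows = order[first.nonzero()[0][counts == 1]]
    for row in boundary_rows:
        a, b = edges[row]
        edge_vec = vertices[b] - vertices[a]
        n = np.cross(edge_vec, edge_face_normal[row])
        norm = np.linalg.norm(n)
        if norm < 1e-14:
            continue
        n = n / norm
        plane_b = np.append(n, -n @ vertices[a])
        kp_b = np.outer(plane_b, plane_b) * _BOUNDARY_WEIGHT
        quadrics[a] += kp_b
        quadrics[b] += kp_b
    return quadrics


def _optimal_points(quadrics_e: np.ndarray, va: np.ndarray, vb: np.ndarray):
    """Optimal collapse position and cost per edge.

    Solves the 3x3 normal system of each summed quadric; falls back to the
    best of {endpoint a, endpoint b, midpoint} where the system is singular
    or the solution strays far from the edge.
    """
    A = quadrics_e[:, :3, :3]
    b = -quadrics_e[:, :3, 3]
    det = np.linalg.det(A)
    solvable = np.abs(det) > 1e-10
    target = (va + vb) / 2.0
    sol = np.copy(target)
    if solvable.any():
        sol[solvable] = np.linalg.solve(A[solvable], b[solvable][:, :, None])[:, :, 0]
    # reject optimal points that run away (nearly singular systems)
    edge_len = np.linalg.norm(vb - va, axis=1)
    runaway = np.linalg.norm(sol - target, axis=1) > np.maximum(4.0 * edge_len, 1e-3)
    sol[runaway] = target[runaway]

    def cost_at(points):
        hom = np.concatenate([points, np.ones((len(points), 1))], axis=1)
        return np.einsum("ij,ijk,ik->i", hom, quadrics_e, hom)

    candidates = np.stack([sol, target, va, vb])  # (4, E, 3)
    costs = np.stack([cost_at(c) for c in candidates])  # (4, E)
    best = np.argmin(costs, axis=0)
    idx = np.arange(costs.shape[1])
    return candidates[best, idx], np.maximum(costs[best, idx], 0.0)


def _unique_edges(faces: np.ndarray):
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    edges, face_count = np.unique(edges, axis=0, return_counts=True)
    return edges, face_count


def _collapsible(edges: np.ndarray, edge_faces: np.ndarray, faces: np.ndarray,
                 n_vertices: int) -> np.ndarray:
    """Link condition: common neighbours of the endpoints must all be
    opposite vertices of faces on the edge, else the collapse pinches the
    surface into a non-manifold configuration."""
    rows = faces.ravel()
    cols = np.roll(faces, -1, axis=1).ravel()
    adj = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(n_vertices, n_vertices),
    ).tocsr()
    adj = adj + adj.T
    adj.data[:] = 1
    common = np.asarray((adj[edges[:, 0]].multiply(adj[edges[:, 1]])).sum(axis=1)).ravel()
    return common == edge_faces


def decimate(vertices: np.ndarray, faces: np.ndarray, target_faces: int,
             max_passes: int = 60):
    """Reduce ``faces`` to at most (and when feasible exactly) ``target_faces``.

    Returns ``(vertices, faces)`` of the decimated mesh.  Deterministic for a
    fixed input; meshes already at or below the target are returned unchanged.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be at least 4")
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if len(faces) <= target_faces:
        return vertices.copy(), faces.copy()

    for _ in range(max_passes):
        excess = len(faces) - target_faces
        if excess <= 0:
            break
        quadrics = _face_quadrics(vertices, faces)
        edges, edge_faces = _unique_edges(faces)
        allowed = _collapsible(edges, edge_faces, faces, len(vertices))
        edges, edge_faces = edges[allowed], edge_faces[allowed]
        if len(edges) == 0:
            break
        va, vb = vertices[edges[:, 0]], vertices[edges[:, 1]]
        points, costs = _optimal_points(quadrics[edges[:, 0]] + quadrics[edges[:, 1]], va, vb)

        order = np.lexsort((edges[:, 1], edges[:, 0], costs))
        # interior edge collapse removes 2 faces; build a vertex-disjoint batch.
        # Small batches keep the pass sequence close to true greedy collapse,
        # which matters for how the budget distributes over curved features
        need = min((excess + 1) // 2, max(1, len(edges) // 12))
        used = np.zeros(len(vertices), dtype=bool)
        batch = []
        for row in order:
            a, b = edges[row]
            if used[a] or used[b]:
                continue
            used[a] = used[b] = True
            batch.append(row)
            if len(batch) >= need:
                break
        if not batch:
            break
        batch = np.array(batch)

        # cap the batch so we cannot overshoot far below the target
        remap = np.arange(len(vertices))
        remap[edges[batch, 1]] = edges[batch, 0]
        vertices = vertices.copy()
        vertices[edges[batch, 0]] = points[batch]

        new_faces = remap[faces]
        degenerate = (
            (new_faces[:, 0] == new_faces[:, 1])
            | (new_faces[:, 1] == new_faces[:, 2])
            | (new_faces[:, 2] == new_faces[:, 0])
        )
        candidate = new_faces[~degenerate]
        if len(candidate) < target_faces:
            # the batch overshot: replay it partially, largest-cost edges first out
            overshoot = target_faces - len(candidate)
            drop = max(1, (overshoot + 1) // 2)
            batch = batch[: max(0, len(batch) - drop)]
            if len(batch) == 0:
                break
            remap = np.arange(len(vertices))
            remap[edges[batch, 1]] = edges[batch, 0]
            new_faces = remap[faces]
            degenerate = (
                (new_faces[:, 0] == new_faces[:, 1])
                | (new_faces[:, 1] == new_faces[:, 2])
                | (new_faces[:, 2] == new_faces[:, 0])
            )
            candidate = new_faces[~degenerate]
        faces = candidate
        # collapses can fold two faces onto each other (a fin); removing
        # both copies keeps a closed surface closed
        fs = np.sort(faces, axis=1)
        _, inverse, counts = np.unique(
            fs, axis=0, return_inverse=True, return_counts=True
        )
        if (counts > 1).any():
            faces = faces[counts[inverse] == 1]

    # compact unused vertices
    used = np.zeros(len(vertices), dtype=bool)
    used[faces.ravel()] = True
    index = np.cumsum(used) - 1
    return vertices[used], index[faces]
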