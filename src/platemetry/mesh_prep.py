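"""Mesh preparation: weld, decimate, join/clean components, recenter.

Scanned appliances arrive as facet soup with duplicate vertices, scanner
artefact blobs and far more triangles than the measurement needs.  The
preparation chain mirrors the original workflow: weld coincident vertices,
reduce the face count to a fixed budget (default 3000), join the remaining
connected components into one entity while discarding artefact blobs, and
recenter the part.  Every step is deterministic for fixed input bytes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import trimesh

from ._decimate import decimate

log = logging.getLogger("platemetry")


@dataclasses.dataclass
class PrepConfig:
    """Parameters of the preparation chain.

    weld_tolerance
        Vertices closer than this (mm) are merged into one index.
    target_faces
        Face budget of the decimation step.
    drop_artifact_fraction
        Connected components whose surface area falls below this fraction of
        the total are treated as scan artefacts and removed.
    recenter_mode
        ``first_face_centre`` moves the centroid of face 0 to the origin
        (mirroring the original tool), ``mesh_centroid`` the area centroid,
        ``none`` leaves the mesh in place.
    """

    weld_tolerance: float = 1e-6
    target_faces: int = 3000
    drop_artifact_fraction: float = 0.001
    recenter_mode: str = "first_face_centre"

    def __post_init__(self):
        if self.weld_tolerance <= 0:
            raise ValueError("weld_tolerance must be positive")
        if self.target_faces < 4:
            raise ValueError("target_faces must be at least 4")
        if not (0.0 <= self.drop_artifact_fraction < 0.5):
            raise ValueError("drop_artifact_fraction must be in [0, 0.5)")
        if self.recenter_mode not in ("first_face_centre", "mesh_centroid", "none"):
            raise ValueError(f"unknown recenter_mode {self.recenter_mode!r}")


def weld_mesh(mesh: trimesh.Trimesh, tolerance: float = 1e-6) -> trimesh.Trimesh:
    """Merge vertices closer than ``tolerance`` into shared indices.

    Positional merging with a small tolerance reproduces the original
    angle-pi weld (which merges every coincident crease vertex) while being
    well defined on facet soup.  Total surface area is preserved; degenerate
    faces created by merging are dropped with a warning.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    digits = max(0, int(round(-np.log10(tolerance))))
    key = np.round(np.asarray(mesh.vertices, dtype=float), digits)
    _, first, inverse = np.unique(
        key.view([("x", float), ("y", float), ("z", float)]).ravel(),
        return_index=True,
        return_inverse=True,
    )
    vertices = np.asarray(mesh.vertices, dtype=float)[first]
    faces = inverse[np.asarray(mesh.faces)]
    degenerate = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 2] == faces[:, 0])
    )
    if degenerate.any():
        log.warning("weld_mesh: dropping %d degenerate face(s)", int(degenerate.sum()))
        faces = faces[~degenerate]
    out = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    out.metadata.update(mesh.metadata)
    return out


def reduce_mesh(mesh: trimesh.Trimesh, target_faces: int = 3000) -> trimesh.Trimesh:
    """Quadric edge-collapse decimation to a hard face-count cap.

    Meshes already at or below the target are returned unchanged; otherwise
    the result has exactly ``target_faces`` faces whenever collapse is
    feasible.  Boundary edges are constraint-weighted so open rims keep their
    shape.
    """
    vertices, faces = decimate(mesh.vertices, mesh.faces, target_faces)
    out = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    out.metadata.update(mesh.metadata)
    return out


def join_and_clean(mesh: trimesh.Trimesh, drop_artifact_fraction: float = 0.001) -> trimesh.Trimesh:
    """Join connected components into one entity, dropping artefact blobs.

    Components whose surface area is below ``drop_artifact_fraction`` of the
    total are removed with a logged warning (scanner artefacts); everything
    else is concatenated into a single mesh entity.
    """
    components = mesh.split(only_watertight=False)
    if len(components) <= 1:
        return mesh
    areas = np.array([c.area for c in components])
    # deterministic order: by descending area then first-vertex lexicographic
    order = np.lexsort((np.arange(len(components)), -areas))
    components = [components[i] for i in order]
    areas = areas[order]
    keep = areas >= drop_artifact_fraction * areas.sum()
    if not keep.any():
        raise ValueError("join_and_clean removed every component")
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning(
            "join_and_clean: dropping %d artefact component(s) (%.4g%% of area)",
            n_dropped,
            100 * areas[~keep].sum() / areas.sum(),
        )
    out = trimesh.util.concatenate([c for c, k in zip(components, keep) if k])
    out.metadata.update(mesh.metadata)
    return out


def recenter_mesh(mesh: trimesh.Trimesh, mode: str = "first_face_centre"):
    """Translate the mesh per ``mode``; returns ``(mesh, translation)``.

    The same translation must be applied to any landmarks used downstream;
    all measurements are invariant to this step.
    """
    if mode == "none":
        translation = np.zeros(3)
    elif mode == "first_face_centre":
        translation = -np.asarray(mesh.triangles_center[0], dtype=float)
    elif mode == "mesh_centroid":
        translation = -np.asarray(mesh.centroid, dtype=float)
    else:
        raise ValueError(f"unknown recenter mode {mode!r}")
    out = mesh.copy()
    out.apply_translation(translation)
    return out, translation


def prepare_mesh(mesh: trimesh.Trimesh, config: PrepConfig | None = None):
    """Run the full preparation chain; returns ``(mesh, translation)``."""
    config = config or PrepConfig()
    welded = weld_mesh(mesh, config.weld_tolerance)
    joined = join_and_clean(welded, config.drop_artifact_fraction)
    reduced = reduce_mesh(joined, config.target_faces)
    return recenter_mesh(reduced, config.recenter_mode)
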