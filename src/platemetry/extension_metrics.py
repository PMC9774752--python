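"""Orchestration of the full measurement: sections, lengths, angles, volume.

The velopharyngeal extension is measured relative to the main base plane
(MBP).  Five section planes parallel to the MBP span the effective extension
from the plane (S1, effective length 0) to the drop of the tip (S5); S1-S4
are fully measured (area, width, thickness, centroid), S5 is the tip itself
(its centroid is the END landmark, only lengths are reported).  On the
opposite side of the plane, the cleft extension is divided into five equal
segments along the sagittal axis and the smallest of the four interior
cross-sections becomes S0.  Centroids chained from the incisive papilla form
the extension skeleton, whose turn angles are reported in degrees, and the
effective extension volume is the watertight clipped solid below the plane.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import trimesh

from .cross_section import (
    SectionError,
    SectionPlane,
    SectionResult,
    measure_section,
)
from .mesh_io import LandmarkSet, MeasurementRecord
from .mesh_prep import join_and_clean, reduce_mesh, weld_mesh
from .reference_frame import ReferenceFrame, build_frame, snap_landmarks

log = logging.getLogger("platemetry")

#: coordinates are rounded to this grid (mm) in the canonical pose so the
#: decimation sequence is bit-stable under rigid motion of the input
_CANONICAL_GRID = 1e-6


class MeasurementError(ValueError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class MeasureConfig:
    """All tunable parameters of the measurement pipeline."""

    n_effective_sections: int = 5
    n_cleft_segments: int = 5
    snap_max_distance: float = 2.0  # mm
    weld_tolerance: float = 1e-6  # mm
    target_faces: int = 3000
    decimate: bool = True
    drop_artifact_fraction: float = 0.001
    chain_tol: float = 1e-6  # mm, loop chaining
    close_gap: float = 0.5  # mm, open-chain closing
    cleft_min_protrusion: float = 3.0  # mm above the MBP to count as cleft material
    signed_angles: bool = False  # sagittal-projection signed variant

    def __post_init__(self):
        if self.n_effective_sections < 2:
            raise ValueError("n_effective_sections must be at least 2")
        if self.n_cleft_segments < 2:
            raise ValueError("n_cleft_segments must be at least 2")

    @classmethod
    def from_file(cls, path) -> "MeasureConfig":
        """Parse a flat ``key = value`` (INI/TOML-style) config file."""
        values = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            if fields[key] in ("bool", bool):
                values[key] = raw.lower() in ("1", "true", "yes", "on")
            elif fields[key] in ("int", int):
                values[key] = int(raw)
            else:
                values[key] = float(raw)
        return cls(**values)


@dataclasses.dataclass
class SkeletonChain:
    """The extension skeleton: IP followed by the section centroids PS_1..PS_N."""

    points: np.ndarray  # (N+1, 3)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 3:
            raise ValueError("skeleton needs at least 3 points (IP, PS_1, PS_2)")
        seg = np.diff(self.points, axis=0)
        if (np.linalg.norm(seg, axis=1) <= 1e-6).any():
            raise ValueError("skeleton contains a zero-length segment")

    @property
    def segments(self) -> np.ndarray:
        return np.diff(self.points, axis=0)


def _tip_section(end_point: np.ndarray, offset: float) -> SectionResult:
    """The S5 tip entry: centroid fixed at END, no area/width/thickness."""
    return SectionResult(
        loop=None,
        centroid=np.asarray(end_point, dtype=float),
        area=None,
        width=None,
        thickness=None,
        width_endpoints=None,
        thickness_endpoints=None,
        offset=offset,
    )


def effective_sections(
    mesh: trimesh.Trimesh,
    frame: ReferenceFrame,
    landmarks: LandmarkSet,
    config: MeasureConfig | None = None,
) -> list[SectionResult]:
    """Measure the sections S1..S_N along the effective extension.

    Planes share the MBP normal at equally spaced offsets (k-1) * D / (N-1),
    so S1 lies in the base plane (EL_1 = 0) and S_N at the drop of the tip.
    The loop belonging to the extension is attributed by proximity to the
    anchor line through the projected END along the normal.  The final
    section is the tip itself: its centroid is the END landmark and it
    carries no area/width/thickness (a cutting plane exactly at the tip is
    degenerate).
    """
    config = config or MeasureConfig()
    n = config.n_effective_sections
    drop = frame.drop
    end_foot = frame.project(landmarks.end)  # E0: END projected onto the MBP
    results: list[SectionResult] = []
    for k in range(1, n + 1):
        offset = (k - 1) * drop / (n - 1)
        if k == n:
            results.append(_tip_section(landmarks.end, offset))
            break
        plane = SectionPlane(
            origin=frame.origin + offset * frame.normal,
            normal=frame.normal,
            u=frame.mediolateral,  # width
            v=frame.sagittal,  # thickness
        )
        anchor = end_foot + offset * frame.normal
        try:
            results.append(
                measure_section(
                    mesh, plane, anchor, offset,
                    chain_tol=config.chain_tol, close_gap=config.close_gap,
                )
            )
        except SectionError as exc:
            raise MeasurementError(f"effective section S{k}: {exc}") from exc
    return results


def _clip_half_space(mesh: trimesh.Trimesh, frame: ReferenceFrame, side: str):
    """Open submesh on one side of the MBP; 'above' is the cleft side."""
    normal = -frame.normal if side == "above" else frame.normal
    clipped = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=frame.origin, cap=False
    )
    if clipped is None or len(clipped.faces) == 0:
        return []
    # the slicer leaves duplicate vertices along the cut, which would tear
    # the cut collar into single-face components
    clipped = weld_mesh(clipped, 1e-7)
    return clipped.split(only_watertight=False)


def cleft_candidates(
    mesh: trimesh.Trimesh,
    frame: ReferenceFrame,
    landmarks: LandmarkSet,
    config: MeasureConfig | None = None,
) -> list[SectionResult]:
    """All candidate cross-sections of the cleft extension (may be empty).

    The cleft sub-mesh is the connected component above the MBP whose
    attachment loop at the plane lies nearest the projected END; fragments
    protruding less than ``cleft_min_protrusion`` above the plane (scan
    ripple, the extension's plane-crossing collar) and floating fragments
    with no attachment at the plane are not cleft material.  Candidate
    planes have the sagittal axis as normal and sit at the interior
    boundaries of ``n_cleft_segments`` equal spans of the component's
    sagittal extent; each is measured with width along the mediolateral and
    thickness along the normal axis.  Candidates slice the full mesh so
    their loops close even where the cleft tube crosses the base plane.
    """
    config = config or MeasureConfig()
    end_foot = frame.project(landmarks.end)
    components = _clip_half_space(mesh, frame, "above")

    chosen = None
    best_key = None
    for comp in components:
        heights = -frame.height(comp.vertices)  # positive above the plane
        if heights.max() < config.cleft_min_protrusion:
            continue
        boundary = comp.vertices[np.abs(heights) < 10 * config.chain_tol + 1e-3]
        if len(boundary) == 0:
            continue  # floating fragment, not attached at the plane
        attach = boundary.mean(axis=0)
        key = (round(float(np.linalg.norm(attach - end_foot)), 9), tuple(np.round(attach, 6)))
        if best_key is None or key < best_key:
            best_key, chosen = key, comp
    if chosen is None:
        log.warning("find_cleft_section: no cleft material above the base plane")
        return []

    s = frame.to_plane_coords(chosen.vertices)[:, 0]
    s_min, s_max = float(s.min()), float(s.max())
    span = (s_max - s_min) / config.n_cleft_segments
    candidates: list[SectionResult] = []
    for i in range(1, config.n_cleft_segments):
        c = s_min + i * span
        plane = SectionPlane(
            origin=frame.origin + c * frame.sagittal,
            normal=frame.sagittal,
            u=frame.mediolateral,  # width
            v=frame.normal,  # thickness
        )
        nearby = chosen.vertices[np.abs(s - c) < span / 2]
        anchor = (
            nearby.mean(axis=0)
            if len(nearby)
            else chosen.vertices[np.argmin(np.abs(s - c))]
        )
        try:
            candidates.append(
                measure_section(
                    mesh, plane, anchor, c,
                    chain_tol=config.chain_tol, close_gap=config.close_gap,
                )
            )
        except SectionError as exc:
            log.warning("cleft candidate at s=%.2f mm skipped: %s", c, exc)
    return candidates


def find_cleft_section(
    mesh: trimesh.Trimesh,
    frame: ReferenceFrame,
    landmarks: LandmarkSet,
    config: MeasureConfig | None = None,
) -> SectionResult | None:
    """The minimal-area cleft cross-section S0, or None when absent.

    Areas of all candidates are compared and the smallest selected; exact
    ties go to the anterior-most (smallest sagittal position) candidate.
    """
    candidates = cleft_candidates(mesh, frame, landmarks, config)
    if not candidates:
        return None
    return min(candidates, key=lambda r: (round(r.area, 6), r.offset))


def compute_lengths(frame: ReferenceFrame, centroids: dict[int, np.ndarray]):
    """Effective and sagittal lengths per section.

    EL_k is the unsigned distance of the centroid PS_k from the MBP; SL_k is
    the in-plane distance from IP to the projection of PS_k onto the plane.
    Returns two dicts keyed like ``centroids``.
    """
    el, sl = {}, {}
    for k, ps in centroids.items():
        coords = frame.to_plane_coords(ps).ravel()
        el[k] = abs(float(coords[2]))
        sl[k] = float(math.hypot(coords[0], coords[1]))
    return el, sl


def compute_angles(
    skeleton: SkeletonChain,
    frame: ReferenceFrame | None = None,
    signed: bool = False,
) -> np.ndarray:
    """Turn angles between consecutive skeleton segments, in degrees.

    The default is the unsigned 3D angle in [0, 180] (collinear segments give
    0).  With ``signed=True`` and a frame, angles are measured in the
    sagittal plane projection with a clockwise-positive sign convention; the
    record always stores magnitudes.
    """
    segments = skeleton.segments
    angles = []
    for a, b in zip(segments[:-1], segments[1:]):
        if signed and frame is not None:
            a2 = np.array([a @ frame.sagittal, a @ frame.normal])
            b2 = np.array([b @ frame.sagittal, b @ frame.normal])
            angle = math.degrees(
                math.atan2(a2[0] * b2[1] - a2[1] * b2[0], a2 @ b2)
            )
        else:
            cosine = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            angle = math.degrees(math.acos(np.clip(cosine, -1.0, 1.0)))
        angles.append(angle)
    return np.asarray(angles)


def _boundary_cycles(faces: np.ndarray):
    """Directed boundary edges of an open mesh, chained into cycles.

    Vertices where several boundary loops touch are followed edge by edge
    (each directed edge used once).  Returns None when the boundary cannot
    be decomposed into closed cycles, in which case the solid cannot be
    capped watertight.
    """
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    counts = {}
    for a, b in edges:
        k = (min(a, b), max(a, b))
        counts[k] = counts.get(k, 0) + 1
    boundary = [
        (int(a), int(b)) for a, b in edges if counts[(min(a, b), max(a, b))] == 1
    ]
    if not boundary:
        return []
    succ: dict[int, list[int]] = {}
    for a, b in boundary:
        succ.setdefault(a, []).append(b)
    for targets in succ.values():
        targets.sort()
    used = set()
    cycles = []
    for a, b in sorted(boundary):
        if (a, b) in used:
            continue
        chain = [(a, b)]
        used.add((a, b))
        node = b
        while node != a:
            step = next(
                (x for x in succ.get(node, []) if (node, x) not in used), None
            )
            if step is None:
                return None  # open boundary: not closable
            chain.append((node, step))
            used.add((node, step))
            node = step
        if len(chain) < 3:
            return None
        cycles.append(chain)
    return cycles


def _cap_components(clipped_components, plane_origin=None, plane_normal=None,
                    plane_tol=1e-4):
    """Fan-cap the planar boundary loops of each clipped component.

    A fan from the loop's vertex centroid is exact for the divergence-theorem
    volume of a planar cap and closes the surface topologically, regardless
    of loop convexity.  When the clip plane is given, only boundary loops
    lying on it are capped; any other boundary means the solid was open
    before clipping (a scan hole), and None is returned for it.
    """
    capped = []
    for comp in clipped_components:
        vertices = np.asarray(comp.vertices, dtype=float)
        faces = np.asarray(comp.faces, dtype=np.int64)
        cycles = _boundary_cycles(faces)
        if cycles is None:
            capped.append(None)
            continue
        new_vertices = [vertices]
        new_faces = [faces]
        offset = len(vertices)
        ok = True
        for cycle in cycles:
            loop_idx = [a for a, _ in cycle]
            if plane_normal is not None:
                height = (vertices[loop_idx] - plane_origin) @ plane_normal
                if np.abs(height).max() > plane_tol:
                    ok = False  # boundary away from the cut: a genuine hole
                    break
            centre = vertices[loop_idx].mean(axis=0)
            new_vertices.append(centre[None, :])
            fan = np.array([[b, a, offset] for a, b in cycle], dtype=np.int64)
            new_faces.append(fan)
            offset += 1
        if not ok:
            capped.append(None)
            continue
        solid = trimesh.Trimesh(
            vertices=np.concatenate(new_vertices),
            faces=np.concatenate(new_faces),
            process=False,
        )
        capped.append(solid)
    return capped


def effective_volume(
    mesh: trimesh.Trimesh,
    frame: ReferenceFrame,
    landmarks: LandmarkSet,
) -> float | None:
    """Volume (mm^3) of the effective extension below the MBP, or None.

    The mesh is clipped to the half-space below the plane, cut cross-sections
    are capped, and among the resulting closed solids the one nearest the
    anchor line through the projected END along the normal is selected.  The
    volume follows from the divergence theorem; a solid that fails to close
    returns None with a warning.
    """
    components = _clip_half_space(mesh, frame, "below")
    if not components:
        log.warning("effective_volume: nothing below the base plane")
        return None
    end_foot = frame.to_plane_coords(frame.project(landmarks.end)).ravel()

    def line_distance(comp):
        rel = frame.to_plane_coords(comp.vertices)
        return float(
            np.hypot(rel[:, 0] - end_foot[0], rel[:, 1] - end_foot[1]).min()
        )

    def depth_extent(comp):
        height = frame.height(comp.vertices)
        return float(height.max() - height.min())

    # the effective extension spans (most of) the drop; tiny cut slivers and
    # the plate shell do not, however close they sit to the anchor line
    candidates = [
        i for i in range(len(components))
        if depth_extent(components[i]) >= 0.5 * frame.drop
    ]
    if not candidates:
        candidates = list(range(len(components)))
    order = sorted(candidates, key=lambda i: (line_distance(components[i]), i))
    selected = components[order[0]]
    solid = _cap_components(
        [selected], plane_origin=frame.origin, plane_normal=frame.normal
    )[0]
    if solid is None or not solid.is_watertight:
        log.warning("effective_volume: clipped extension did not close; volume missing")
        return None
    return float(abs(solid.volume))


@dataclasses.dataclass
class PipelineResult:
    """Everything measure_plate computes, for inspection and testing."""

    record: MeasurementRecord
    frame: ReferenceFrame
    landmarks: LandmarkSet  # snapped, in measurement coordinates
    prepared_mesh: trimesh.Trimesh
    sections: list[SectionResult]
    cleft_section: SectionResult | None
    skeleton: SkeletonChain
    pose: np.ndarray  # world -> measurement 4x4 transform


def _canonical_pose(mesh, landmarks, frame):
    """Re-express mesh and landmarks in the landmark frame, on a 1e-6 grid.

    Measuring in the canonical pose makes every downstream step (including
    greedy decimation, which is sensitive to last-bit coordinate changes)
    reproduce bit-identical results under rigid motion of the input.
    """
    matrix = frame.pose_matrix()
    posed = mesh.copy()
    posed.apply_transform(matrix)
    vertices = np.round(np.asarray(posed.vertices) / _CANONICAL_GRID) * _CANONICAL_GRID
    faces = np.asarray(posed.faces, dtype=np.int64)

    # canonical ordering: vertex/face order must not leak the input pose.
    # np.unique sorts rows lexicographically and merges coordinates that
    # became identical on the grid (they are within weld tolerance anyway)
    vertices, inverse = np.unique(vertices, axis=0, return_inverse=True)
    faces = inverse[faces]
    faces = faces[
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    ]
    roll = np.argmin(faces, axis=1)
    faces = np.stack(
        [faces[np.arange(len(faces)), (roll + i) % 3] for i in range(3)], axis=1
    )
    faces = faces[np.lexsort((faces[:, 2], faces[:, 1], faces[:, 0]))]

    posed = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    lm = landmarks.transformed(matrix)
    lm = LandmarkSet(*(np.round(lm.points() / _CANONICAL_GRID) * _CANONICAL_GRID))
    return posed, lm, matrix


def measure_plate_detailed(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    config: MeasureConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline and return all intermediate products."""
    config = config or MeasureConfig()
    if config.n_effective_sections != 5 or config.n_cleft_segments != 5:
        raise MeasurementError(
            "the 32-value record schema requires 5 effective sections and "
            "5 cleft segments; use the stage functions directly for other counts"
        )

    try:
        welded = weld_mesh(mesh, config.weld_tolerance)
        cleaned = join_and_clean(welded, config.drop_artifact_fraction)
    except ValueError as exc:
        raise MeasurementError(f"mesh preparation: {exc}") from exc

    # landmarks anchor on the full-resolution welded mesh so the frame does
    # not depend on the decimation budget
    snapped = snap_landmarks(cleaned, landmarks, config.snap_max_distance)
    prelim = build_frame(snapped)
    posed_mesh, posed_lm, pose = _canonical_pose(cleaned, snapped, prelim)

    if config.decimate:
        posed_mesh = reduce_mesh(posed_mesh, config.target_faces)
    frame = build_frame(posed_lm)

    sections = effective_sections(posed_mesh, frame, posed_lm, config)
    cleft = find_cleft_section(posed_mesh, frame, posed_lm, config)
    volume = effective_volume(posed_mesh, frame, posed_lm)

    centroids = {k + 1: sec.centroid for k, sec in enumerate(sections)}
    if cleft is not None:
        centroids[0] = cleft.centroid
    el, sl = compute_lengths(frame, centroids)
    if 1 in el and el[1] < 1e-9:
        el[1] = 0.0

    skeleton = SkeletonChain(
        np.vstack([frame.origin] + [sections[k].centroid for k in range(len(sections))])
    )
    try:
        alphas = compute_angles(skeleton, frame, signed=config.signed_angles)
    except ValueError as exc:
        raise MeasurementError(f"skeleton angles: {exc}") from exc

    values = {}
    for k in range(6):
        if k in el:
            values[f"EL_{k}"] = el[k]
            values[f"SL_{k}"] = sl[k]
    for k in range(1, 5):
        sec = sections[k - 1]
        values[f"A_{k}"] = sec.area
        values[f"W_{k}"] = sec.width
        values[f"T_{k}"] = sec.thickness
    if cleft is not None:
        values["A_0"] = cleft.area
        values["W_0"] = cleft.width
        values["T_0"] = cleft.thickness
    if volume is not None:
        values["V_eff"] = volume
    for j, alpha in enumerate(alphas, start=1):
        values[f"alpha_{j}"] = abs(alpha)

    record = MeasurementRecord(
        values=values,
        source_mesh=str(mesh.metadata.get("provenance", "")),
    )
    record.validate()
    return PipelineResult(
        record=record,
        frame=frame,
        landmarks=posed_lm,
        prepared_mesh=posed_mesh,
        sections=sections,
        cleft_section=cleft,
        skeleton=skeleton,
        pose=pose,
    )


def measure_plate(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    config: MeasureConfig | None = None,
) -> MeasurementRecord:
    """Measure an appliance mesh: raw mesh + landmarks -> 32-value record.

    Runs preparation (weld, join/clean, decimate), landmark snapping, frame
    construction, effective sections S1-S5, cleft section S0, lengths,
    skeleton angles and effective volume.  Stages that legitimately find
    nothing (no cleft material, unclosable volume) leave NA values; hard
    failures raise :class:`MeasurementError` naming the stage.
    """
    return measure_plate_detailed(mesh, landmarks, config).record
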