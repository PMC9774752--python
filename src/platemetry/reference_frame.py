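"""Main base plane and measurement axes from the four landmarks.

The main base plane (MBP) passes through the incisive papilla (IP) and the
two tuber-maxilla points (Q1, Q2).  Its normal is oriented toward the
extension tip END, so the "effective" side of the appliance lies at positive
offsets.  The in-plane sagittal axis points toward the projected END, the
mediolateral axis completes a right-handed frame, and the drop D is the
perpendicular distance of END below the plane.  Every downstream measurement
(section offsets, lengths, widths, thicknesses, the effective/cleft split)
is expressed in this frame.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import LandmarkSet

_DEGENERATE_AREA = 1e-6  # mm^2, triangle IP-Q1-Q2
_MIN_DROP = 1e-6  # mm


class FrameError(ValueError):
    """Raised when the landmarks cannot define a usable reference frame."""


@dataclasses.dataclass
class ReferenceFrame:
    """Oriented measurement frame anchored at the incisive papilla.

    ``normal`` points from the plane toward END (unit), ``sagittal`` is the
    in-plane unit vector toward the projected END, ``mediolateral`` is
    ``sagittal x normal`` (right-handed), and ``drop`` is (END - IP) . normal
    in mm (always positive).
    """

    origin: np.ndarray
    normal: np.ndarray
    sagittal: np.ndarray
    mediolateral: np.ndarray
    drop: float

    def height(self, points: np.ndarray) -> np.ndarray:
        """Signed offset of points along the normal (positive toward END)."""
        return (np.asarray(points) - self.origin) @ self.normal

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the main base plane."""
        points = np.asarray(points, dtype=float)
        h = self.height(points)
        return points - np.multiply.outer(h, self.normal)

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        """(sagittal, mediolateral, normal) coordinates relative to IP."""
        rel = np.asarray(points, dtype=float) - self.origin
        return rel @ np.column_stack([self.sagittal, self.mediolateral, self.normal])

    def pose_matrix(self) -> np.ndarray:
        """4x4 transform taking world coordinates into the canonical pose.

        Canonical pose: IP at the origin, sagittal axis = +x, mediolateral
        axis = +y, plane normal = -z (the effective extension descends into
        z < 0, the cleft extension rises into z > 0).
        """
        rotation = np.stack([self.sagittal, self.mediolateral, -self.normal])
        matrix = np.eye(4)
        matrix[:3, :3] = rotation
        matrix[:3, 3] = -rotation @ self.origin
        return matrix


def snap_landmarks(mesh, landmarks: LandmarkSet, max_distance: float = 2.0) -> LandmarkSet:
    """Replace each landmark by the nearest mesh vertex.

    A stand-in for on-screen vertex picking: landmark files carry approximate
    coordinates, the measurement anchors on actual surface vertices.  A
    landmark farther than ``max_distance`` from any vertex is rejected by
    name.  Ties are resolved by lowest vertex index (deterministic).
    """
    vertices = np.asarray(mesh.vertices, dtype=float)
    tree = cKDTree(vertices)
    distances, indices = tree.query(landmarks.points())
    snapped = {}
    for name, dist, idx in zip(("ip", "q1", "q2", "end"), distances, indices):
        if dist > max_distance:
            raise FrameError(
                f"landmark {name.upper()} is {dist:.2f} mm from the nearest mesh "
                f"vertex (limit {max_distance:g} mm)"
            )
        snapped[name] = vertices[idx].copy()
    return LandmarkSet(**snapped)


def build_frame(landmarks: LandmarkSet) -> ReferenceFrame:
    """Construct the main base plane and oriented axes from the landmarks.

    Raises :class:`FrameError` when IP, Q1, Q2 are (near-)collinear, when END
    lies in the plane (zero drop), or when END projects onto IP (undefined
    sagittal direction).
    """
    ip, q1, q2, end = landmarks.ip, landmarks.q1, landmarks.q2, landmarks.end
    cross = np.cross(q1 - ip, q2 - ip)
    area2 = np.linalg.norm(cross)
    if area2 / 2.0 < _DEGENERATE_AREA:
        raise FrameError(
            "IP, Q1, Q2 are collinear (triangle area "
            f"{area2 / 2.0:.3g} mm^2): base plane is degenerate"
        )
    normal = cross / area2
    drop = float((end - ip) @ normal)
    if abs(drop) < _MIN_DROP:
        raise FrameError("END lies in the base plane: drop is zero")
    if drop < 0:
        normal = -normal
        drop = -drop

    in_plane = (end - ip) - drop * normal
    sagittal_len = np.linalg.norm(in_plane)
    if sagittal_len < 1e-9:
        raise FrameError(
            "END projects exactly onto IP: sagittal direction is undefined"
        )
    sagittal = in_plane / sagittal_len
    mediolateral = np.cross(sagittal, normal)
    mediolateral /= np.linalg.norm(mediolateral)
    return ReferenceFrame(
        origin=ip.copy(),
        normal=normal,
        sagittal=sagittal,
        mediolateral=mediolateral,
        drop=drop,
    )
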