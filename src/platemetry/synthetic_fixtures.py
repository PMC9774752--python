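"""Watertight phantom appliances with analytic ground truth.

The original study measured scanned appliances; those scans are not
available, so this module builds stylised stand-ins with the same structure
and known geometry: an elliptical base plate carrying a gentle surface
ripple (whose nodal lines host the landmarks, so the landmark plane is
exactly z = 0), joined to a tube-like velopharyngeal extension.  The
extension rises from the posterior plate edge, arches over the base plane
(the cleft portion, optionally necked so the minimal section S0 has a known
location), crosses the plane and descends as a piecewise-straight effective
portion whose knots sit exactly at the section-plane depths.  Because the
knots coincide with the measurement planes, drop, lengths, turn angles,
section dimensions and clipped volume all have closed forms.

Solids are modelled as signed-distance-style level sets and surfaced by
marching cubes, which guarantees watertight meshes; all randomness (surface
noise, artefact blobs) is seeded and applied as an explicit perturbation
step.  Default dimensions sit in the neonatal range of real appliances
(drops around 20-27 mm, section widths 3-8 mm, thicknesses 2.5-5 mm).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import trimesh
from skimage import measure as _sk_measure

from .mesh_io import LandmarkSet


class PhantomError(ValueError):
    """Raised for unbuildable phantom specifications."""


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic appliance phantom (all lengths in mm).

    The base plate is an ellipse ``plate_semi_axes`` with a downward vault
    bulge and a small surface ripple; the extension is an elliptical tube of
    semi-axes ``tube_width``/``tube_height`` (mediolateral / sagittal-normal)
    that drops ``drop`` mm below the landmark plane, leaving it at
    ``bend_deg`` from the sagittal axis and turning by ``turns_deg`` at the
    three interior section knots.  The cleft arch runs ``cleft_run`` mm along
    the sagittal axis with a Gaussian neck of scale ``neck_scale`` at
    fractional position ``neck_position``.
    """

    plate_semi_axes: tuple = (20.5, 14.5)
    vault_depth: float = 4.0
    shell_thickness: float = 2.0
    ripple_amp: float = 0.05
    ripple_wavelength: float = 9.0

    drop: float = 21.0
    bend_deg: float = 65.0
    turns_deg: tuple = (8.0, 6.0, 15.0)
    tube_width: float = 3.0  # mediolateral semi-axis
    tube_height: float = 2.0  # semi-axis perpendicular to the axis, sagittal plane

    cleft: bool = True
    cleft_run: float = 14.0
    cleft_apex: float = 6.0
    cleft_start_height: float = 1.2
    approach_len: float = 3.0
    neck_position: float = 0.45
    neck_scale: float = 0.62
    neck_halfwidth: float = 3.5

    noise_sigma: float = 0.0
    n_blobs: int = 0
    blob_radius: float = 1.0

    rotation_deg: tuple = (0.0, 0.0, 0.0)
    translation: tuple = (0.0, 0.0, 0.0)

    seed: int = 0
    pitch: float = 0.7

    def __post_init__(self):
        if self.drop <= 0:
            raise PhantomError("drop must be positive")
        if not (0.0 < self.bend_deg < 180.0):
            raise PhantomError("bend_deg must lie in (0, 180)")
        if self.tube_width <= 0 or self.tube_height <= 0:
            raise PhantomError("tube semi-axes must be positive")
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be non-negative")
        thinnest = min(
            self.shell_thickness,
            2 * self.tube_height * (self.neck_scale if self.cleft else 1.0),
            2 * self.tube_width * (self.neck_scale if self.cleft else 1.0),
        )
        if self.pitch > thinnest / 2.5:
            raise PhantomError(
                f"voxel pitch {self.pitch} mm too coarse for thinnest feature "
                f"{thinnest:.2f} mm (need pitch <= {thinnest / 2.5:.2f})"
            )
        betas = self.segment_angles_deg()
        if min(betas) < 10.0 or max(betas) > 170.0:
            raise PhantomError("extension segments too close to the base plane")

    # ------------------------------------------------------------------ axis
    def segment_angles_deg(self) -> np.ndarray:
        """Angle of each effective segment below the sagittal axis (deg)."""
        return self.bend_deg + np.concatenate([[0.0], np.cumsum(self.turns_deg)])

    def effective_knots(self) -> np.ndarray:
        """Axis knots of the effective portion, in canonical coordinates.

        The polyline starts where the extension crosses the landmark plane,
        bends at depths 3D/8, 5D/8 and 7D/8 and ends at the tip depth D.
        Bends sit midway BETWEEN the section planes (0, D/4, D/2, 3D/4, D),
        so every measured section cuts the interior of a straight segment
        and has an exact elliptical cross-section.
        """
        betas = np.radians(self.segment_angles_deg())
        spans = np.array([3.0, 2.0, 2.0, 1.0]) * self.drop / 8.0
        knots = [np.array([self._x_attach() + self.cleft_run, 0.0, 0.0])]
        for beta, dz in zip(betas, spans):
            step = (dz / math.sin(beta)) * np.array(
                [math.cos(beta), 0.0, -math.sin(beta)]
            )
            knots.append(knots[-1] + step)
        return np.asarray(knots)

    def section_centroids(self) -> np.ndarray:
        """Exact axis points at the section depths 0, D/4, D/2, 3D/4, D."""
        knots = self.effective_knots()
        betas = np.radians(self.segment_angles_deg())
        dz = self.drop / 4.0
        return np.asarray(
            [
                knots[0],
                knots[0] + (dz / math.sin(betas[0])) * _direction(betas[0]),
                knots[1] + (0.5 * dz / math.sin(betas[1])) * _direction(betas[1]),
                knots[2] + (0.5 * dz / math.sin(betas[2])) * _direction(betas[2]),
                knots[4],
            ]
        )

    def cleft_knots(self) -> np.ndarray:
        """Axis knots of the cleft arch: start, apex, approach point, P1."""
        p1 = self.effective_knots()[0]
        beta1 = math.radians(self.bend_deg)
        d1 = np.array([math.cos(beta1), 0.0, -math.sin(beta1)])
        c2 = p1 - self.approach_len * d1
        start = np.array([self._x_attach(), 0.0, self.cleft_start_height])
        apex = np.array(
            [start[0] + 0.4 * (c2[0] - start[0]), 0.0, self.cleft_apex]
        )
        return np.asarray([start, apex, c2, p1])

    def axis_knots(self) -> np.ndarray:
        eff = self.effective_knots()
        if self.cleft:
            return np.vstack([self.cleft_knots()[:-1], eff])
        # no cleft: a short collar above the plane so the S1 cut still closes
        beta1 = math.radians(self.bend_deg)
        d1 = np.array([math.cos(beta1), 0.0, -math.sin(beta1)])
        return np.vstack([(eff[0] - 2.5 * d1)[None, :], eff])

    def _x_attach(self) -> float:
        return self.plate_semi_axes[0] - 0.5

    def neck_x(self) -> float:
        return self._x_attach() + self.neck_position * self.cleft_run

    def profile(self, x) -> np.ndarray:
        """Tube scale factor rho(x): a smooth neck along the cleft arch.

        The neck is a compactly supported bump (zero outside
        ``neck_x +- neck_halfwidth``), so the effective portion of the tube
        keeps exactly its nominal cross-section.
        """
        x = np.asarray(x, dtype=float)
        if not self.cleft:
            return np.ones_like(x)
        u = (x - self.neck_x()) / self.neck_halfwidth
        inside = np.abs(u) < 1.0
        bump = np.zeros_like(u)
        u_in = np.clip(u[inside], -0.999999, 0.999999)
        bump[inside] = np.exp(1.0 - 1.0 / (1.0 - u_in**2))
        return 1.0 - (1.0 - self.neck_scale) * bump

    # ------------------------------------------------------------- landmarks
    def _ripple_node(self, x_target: float) -> float:
        """Nearest x where the ripple vanishes identically (cos(kx x) = 0)."""
        half = self.ripple_wavelength / 2.0
        m = round(x_target / half - 0.5)
        return (m + 0.5) * half

    def canonical_landmarks(self) -> LandmarkSet:
        a_p, b_p = self.plate_semi_axes
        x_ip = self._ripple_node(-0.8 * a_p)
        x_q = self._ripple_node(0.55 * a_p)
        y_q = 0.62 * b_p
        end = self.effective_knots()[-1]
        return LandmarkSet(
            ip=[x_ip, 0.0, 0.0],
            q1=[x_q, y_q, 0.0],
            q2=[x_q, -y_q, 0.0],
            end=end,
        )

    def pose_matrix(self) -> np.ndarray:
        matrix = trimesh.transformations.euler_matrix(
            *np.radians(self.rotation_deg), axes="sxyz"
        )
        matrix[:3, 3] = np.asarray(self.translation, dtype=float)
        return matrix


def _direction(beta: float) -> np.ndarray:
    """Unit direction descending at angle beta (radians) below the sagittal axis."""
    return np.array([math.cos(beta), 0.0, -math.sin(beta)])


# ---------------------------------------------------------------- level set
def _ripple(spec: PhantomSpec, x, y):
    k = 2.0 * math.pi / spec.ripple_wavelength
    # the y-asymmetric term breaks mirror symmetry (no tied collapse costs);
    # both terms vanish on the cos(kx) nodal lines that host the landmarks
    return (
        spec.ripple_amp
        * np.cos(k * x)
        * (np.cos(k * y) + 0.35 * np.sin(1.7 * k * y + 0.6))
    )


def _plate_field(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    a_p, b_p = spec.plate_semi_axes
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    e = (x / a_p) ** 2 + (y / b_p) ** 2
    z_top = _ripple(spec, x, y)
    z_bot = -(spec.shell_thickness + spec.vault_depth * np.clip(1.0 - e, 0.0, None))
    radial = np.hypot(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_ell = np.where(e > 0, radial * (1.0 - 1.0 / np.sqrt(np.maximum(e, 1e-12))), -b_p)
    return np.maximum.reduce([z - z_top, z_bot - z, d_ell])


def _tube_field_raw(pts: np.ndarray, knots: np.ndarray, w, h) -> np.ndarray:
    """Union of elliptical cylinders along a knot polyline, miter-jointed.

    Interior joints are bounded by the bisector plane of the adjacent
    directions (a miter joint), so consecutive segments meet in a clean
    seam with no degenerate level-set membrane, and the swept volume is
    exactly pi*w*h*(polyline length); the free ends carry perpendicular
    caps.  ``w``/``h`` may vary per point (profile necking); the polyline
    must lie in the sagittal (x-z) plane.
    """
    # drop interior knots where the polyline does not actually turn: a joint
    # between collinear segments would re-introduce a degenerate level-set
    # membrane in the union below
    kept = [np.asarray(knots[0], dtype=float)]
    for i in range(1, len(knots) - 1):
        d_prev = knots[i] - kept[-1]
        d_next = knots[i + 1] - knots[i]
        d_prev = d_prev / np.linalg.norm(d_prev)
        d_next = d_next / np.linalg.norm(d_next)
        if d_prev @ d_next < 1.0 - 1e-12:
            kept.append(np.asarray(knots[i], dtype=float))
    kept.append(np.asarray(knots[-1], dtype=float))
    knots = np.vstack(kept)

    directions = np.diff(knots, axis=0)
    lengths = np.linalg.norm(directions, axis=1)
    directions = directions / lengths[:, None]
    n_seg = len(directions)
    joint_normals = [directions[0]]
    for i in range(1, n_seg):
        m = directions[i - 1] + directions[i]
        joint_normals.append(m / np.linalg.norm(m))
    joint_normals.append(directions[-1])

    field = np.full(len(pts), np.inf)
    for i in range(n_seg):
        p0, p1 = knots[i], knots[i + 1]
        d = directions[i]
        e_h = np.array([d[2], 0.0, -d[0]])  # unit, in the sagittal plane
        rel0 = pts - p0
        a = rel0 @ e_h
        b = rel0[:, 1]
        q = np.sqrt((a / h) ** 2 + (b / w) ** 2)
        radial = (q - 1.0) * np.minimum(w, h)
        lo = -(rel0 @ joint_normals[i])
        hi = (pts - p1) @ joint_normals[i + 1]
        field = np.minimum(field, np.maximum.reduce([radial, lo, hi]))
    return field


def _tube_field(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    rho = spec.profile(pts[:, 0])
    return _tube_field_raw(
        pts, spec.axis_knots(), spec.tube_width * rho, spec.tube_height * rho
    )


def _surface_level_set(field_fn, bounds_lo, bounds_hi, pitch) -> trimesh.Trimesh:
    """Sample a level-set field on a grid and surface it by marching cubes."""
    lo = np.asarray(bounds_lo, dtype=float) - 2.0 * pitch
    hi = np.asarray(bounds_hi, dtype=float) + 2.0 * pitch
    # snap the origin to a pitch grid with a fixed fractional offset so no
    # sample lands exactly on the z = 0 landmark plane
    origin = np.floor(lo / pitch) * pitch - 0.37 * pitch
    shape = np.ceil((hi - origin) / pitch).astype(int) + 1
    axes = [origin[i] + pitch * np.arange(shape[i]) for i in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grid], axis=1)
    values = field_fn(pts).reshape(shape)
    if values.min() > 0 or values.max() < 0:
        raise PhantomError("level set does not cross zero inside the grid")
    verts, faces, _, _ = _sk_measure.marching_cubes(
        values, level=0.0, spacing=(pitch, pitch, pitch)
    )
    verts = verts + origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# -------------------------------------------------------------------- truth
@dataclasses.dataclass
class PhantomTruth:
    """Closed-form expectations for a phantom, with per-quantity tolerances.

    Tolerances are declared by the generator (relative unless the quantity is
    an angle, which uses degrees): they cover marching-cubes faceting,
    decimation to the 3000-face budget and landmark quantization.
    """

    drop: float
    el: dict
    sl: dict
    area: dict
    width: dict
    thickness: dict
    alphas: np.ndarray
    v_eff: float
    s0: dict | None  # area/width/thickness/position of the expected S0
    landmarks: LandmarkSet  # exact canonical landmark coordinates
    seed: int
    tolerances: dict = dataclasses.field(default_factory=dict)

    def expected_record(self) -> list:
        """(record key, expected value, absolute tolerance) triples."""
        tol = self.tolerances
        out = [("EL_1", 0.0, 1e-6)]
        for k in range(2, 6):
            out.append((f"EL_{k}", self.el[k], tol["el"] * self.el[k]))
        for k in range(1, 6):
            out.append((f"SL_{k}", self.sl[k], tol["sl"] * self.sl[k]))
        for k in range(1, 5):
            out.append((f"A_{k}", self.area[k], tol["area"] * self.area[k]))
            out.append((f"W_{k}", self.width[k], tol["width"] * self.width[k]))
            out.append((f"T_{k}", self.thickness[k], tol["thickness"] * self.thickness[k]))
        for j in range(4):
            out.append((f"alpha_{j + 1}", float(self.alphas[j]), tol["alpha_deg"]))
        out.append(("V_eff", self.v_eff, tol["v_eff"] * self.v_eff))
        if self.s0 is not None:
            for key, name in (("A_0", "area"), ("W_0", "width"), ("T_0", "thickness")):
                out.append((key, self.s0[name], tol["s0"] * self.s0[name]))
        return out


def _axis_at_x(knots: np.ndarray, x: float):
    """Height and direction of a piecewise-linear, x-monotone axis at x."""
    for p0, p1 in zip(knots[:-1], knots[1:]):
        if p0[0] <= x <= p1[0]:
            frac = (x - p0[0]) / (p1[0] - p0[0])
            z = p0[2] + frac * (p1[2] - p0[2])
            d = (p1 - p0) / np.linalg.norm(p1 - p0)
            return z, d
    raise PhantomError(f"x={x} outside the cleft axis range")


def _compute_truth(spec: PhantomSpec) -> PhantomTruth:
    betas = np.radians(spec.segment_angles_deg())
    knots = spec.effective_knots()
    centroids = spec.section_centroids()
    lm = spec.canonical_landmarks()
    w, h = spec.tube_width, spec.tube_height
    dz = spec.drop / 4.0

    el = {k: (k - 1) * dz for k in range(1, 6)}
    sl = {k: float(abs(centroids[k - 1][0] - lm.ip[0])) for k in range(1, 6)}

    # sections at depths 0 and D/4 cut segment 1, D/2 segment 2, 3D/4 segment 3
    csc = 1.0 / np.sin(betas)
    section_csc = {1: csc[0], 2: csc[0], 3: csc[1], 4: csc[2]}
    area = {k: math.pi * w * h * c for k, c in section_csc.items()}
    thickness = {k: 2.0 * h * c for k, c in section_csc.items()}
    width = {k: 2.0 * w for k in range(1, 5)}

    # skeleton turn angles from the exact centroid chain (chords straddle the
    # axis bends, so only alpha_1 equals the nominal bend exactly)
    chain = np.vstack([lm.ip, centroids])
    segments = np.diff(chain, axis=0)
    alphas = []
    for a, b in zip(segments[:-1], segments[1:]):
        cosine = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        alphas.append(math.degrees(math.acos(max(-1.0, min(1.0, cosine)))))
    alphas = np.asarray(alphas)

    # miter-jointed sweep: volume is exactly cross-section area times path
    # length (the bisector cut gains and loses congruent wedges)
    seg_spans = np.array([3.0, 2.0, 2.0, 1.0]) * spec.drop / 8.0
    v_eff = math.pi * w * h * float((seg_spans * csc).sum())

    s0 = None
    if spec.cleft:
        arch = spec.cleft_knots()
        beta1 = math.radians(spec.bend_deg)
        delta1 = math.atan2(arch[1][2] - arch[0][2], arch[1][0] - arch[0][0])
        x_lo = arch[0][0] - h * math.sin(delta1)
        x_hi = knots[0][0] + h / math.sin(beta1)
        candidates = []
        for i in range(1, 5):
            c = x_lo + i * (x_hi - x_lo) / 5.0
            rho = float(spec.profile(c))
            _, d = _axis_at_x(np.vstack([arch[:-1], knots]), c)
            cos_psi = abs(d[0])
            candidates.append(
                {
                    "position": c,
                    "area": math.pi * (w * rho) * (h * rho) / cos_psi,
                    "width": 2.0 * w * rho,
                    "thickness": 2.0 * h * rho / cos_psi,
                }
            )
        s0 = min(candidates, key=lambda cand: cand["area"])

    return PhantomTruth(
        drop=spec.drop,
        el=el,
        sl=sl,
        area=area,
        width=width,
        thickness=thickness,
        alphas=alphas,
        v_eff=v_eff,
        s0=s0,
        landmarks=lm,
        seed=spec.seed,
        tolerances={
            "el": 0.02,
            "sl": 0.05,
            "area": 0.06,
            "width": 0.05,
            "thickness": 0.05,
            "alpha_deg": 3.0,
            "v_eff": 0.05,
            "s0": 0.15,
        },
    )


# ---------------------------------------------------------------- builders
def make_phantom(spec: PhantomSpec | None = None):
    """Build a phantom appliance; returns ``(mesh, landmarks, truth)``.

    The mesh is watertight at zero noise, deterministic for a fixed seed, and
    carries the requested rigid transform (as do the landmarks; the truth
    stores pose-invariant quantities plus the canonical landmark positions).
    """
    spec = spec or PhantomSpec()
    a_p, b_p = spec.plate_semi_axes
    knots = spec.axis_knots()
    r = max(spec.tube_width, spec.tube_height)
    lo = np.minimum(
        [-a_p, -b_p, -(spec.shell_thickness + spec.vault_depth)],
        knots.min(axis=0) - r,
    )
    hi = np.maximum([a_p, b_p, spec.ripple_amp], knots.max(axis=0) + r)

    def field(pts):
        return np.minimum(_plate_field(spec, pts), _tube_field(spec, pts))

    mesh = _surface_level_set(field, lo, hi, spec.pitch)
    truth = _compute_truth(spec)
    landmarks = truth.landmarks

    if spec.noise_sigma > 0 or spec.n_blobs > 0:
        mesh = apply_perturbations(mesh, spec)

    matrix = spec.pose_matrix()
    if not np.allclose(matrix, np.eye(4)):
        mesh = mesh.copy()
        mesh.apply_transform(matrix)
        landmarks = landmarks.transformed(matrix)
    mesh.metadata["provenance"] = f"phantom(seed={spec.seed})"
    return mesh, landmarks, truth


def apply_perturbations(mesh: trimesh.Trimesh, spec: PhantomSpec) -> trimesh.Trimesh:
    """Scan-like degradation: seeded normal jitter plus artefact blobs.

    Vertex positions move along their (angle-weighted) vertex normals by
    N(0, sigma^2); disconnected icosphere blobs are appended outside the
    part.  The result may be non-watertight, which is the point: it feeds
    the robustness paths of the preparation chain.
    """
    rng = np.random.default_rng(spec.seed)
    out = mesh.copy()
    if spec.noise_sigma > 0:
        jitter = rng.normal(0.0, spec.noise_sigma, size=len(out.vertices))
        out = trimesh.Trimesh(
            vertices=np.asarray(out.vertices) + out.vertex_normals * jitter[:, None],
            faces=out.faces,
            process=False,
        )
    if spec.n_blobs > 0:
        pieces = [out]
        base = out.bounds[1] + spec.blob_radius * 4.0
        for i in range(spec.n_blobs):
            blob = trimesh.creation.icosphere(subdivisions=1, radius=spec.blob_radius)
            offset = base + np.array([i * 4.0 * spec.blob_radius, 0.0, 0.0])
            blob.apply_translation(offset + rng.normal(0.0, 0.3, size=3))
            pieces.append(blob)
        out = trimesh.util.concatenate(pieces)
    out.metadata.update(mesh.metadata)
    return out


def make_primitive(kind: str, resolution: int = 64, **params):
    """Reference solids with closed-form truth: cylinder, sphere, box, tube.

    Returns ``(mesh, truth_dict)``; cylinders and spheres are polyhedral
    approximations, so mesh area/volume converge to the closed forms as
    ``resolution`` grows.
    """
    if kind == "cylinder":
        r, height = params["radius"], params["height"]
        if r <= 0 or height <= 0:
            raise ValueError("cylinder needs positive radius and height")
        mesh = trimesh.creation.cylinder(radius=r, height=height, sections=resolution)
        truth = {
            "volume": math.pi * r * r * height,
            "area": 2 * math.pi * r * height + 2 * math.pi * r * r,
            "section_area": math.pi * r * r,
        }
    elif kind == "sphere":
        r = params["radius"]
        if r <= 0:
            raise ValueError("sphere needs positive radius")
        subdivisions = max(2, int(math.log2(max(resolution, 8)) - 1))
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=r)
        truth = {
            "volume": 4.0 / 3.0 * math.pi * r**3,
            "area": 4.0 * math.pi * r**2,
            "section_area": math.pi * r * r,
        }
    elif kind == "box":
        extents = np.asarray(params["extents"], dtype=float)
        if (extents <= 0).any():
            raise ValueError("box needs positive extents")
        mesh = trimesh.creation.box(extents=extents)
        truth = {
            "volume": float(np.prod(extents)),
            "area": float(2 * (extents[0] * extents[1] + extents[1] * extents[2] + extents[0] * extents[2])),
        }
    elif kind == "tube":
        knots = np.asarray(params["knots"], dtype=float)
        w, h = params.get("width", 3.0), params.get("height", 2.0)
        pitch = params.get("pitch", 0.5)
        if w <= 0 or h <= 0:
            raise ValueError("tube needs positive semi-axes")

        def field(pts):
            return _tube_field_raw(pts, knots, w, h)

        mesh = _surface_level_set(
            field, knots.min(axis=0) - max(w, h), knots.max(axis=0) + max(w, h), pitch
        )
        length = float(np.linalg.norm(np.diff(knots, axis=0), axis=1).sum())
        truth = {"volume": math.pi * w * h * length, "length": length}
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    return mesh, truth
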