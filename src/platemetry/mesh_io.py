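"""Reading and writing the formats the measurement pipeline touches.

Three kinds of artefact move in and out of the pipeline: triangle meshes of
scanned appliances (STL, binary or ASCII, coordinates in millimetres),
landmark files (JSON objects naming the four anatomical reference points),
and the exported measurement record (CSV or JSON, 32 values per appliance).

Meshes are represented as :class:`trimesh.Trimesh` throughout; readers return
the raw facet soup exactly as stored so that downstream welding is an explicit,
tested step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__

log = logging.getLogger("platemetry")

LANDMARK_NAMES = ("IP", "Q1", "Q2", "END")

#: Fixed column order of the 32 measurement values in exported records.
RECORD_COLUMNS = tuple(
    [f"{q}_{k}" for k in range(5) for q in ("EL", "SL", "A", "W", "T")]
    + ["EL_5", "SL_5", "V_eff", "alpha_1", "alpha_2", "alpha_3", "alpha_4"]
)

#: Leading metadata columns written before the measurement columns.
META_COLUMNS = ("source_mesh", "landmark_file", "tool_version")


class MeshIOError(ValueError):
    """Raised for malformed or unreadable input files."""


def read_stl(path) -> trimesh.Trimesh:
    """Read an STL file (binary or ASCII) as a raw, unwelded triangle mesh.

    Coordinates are interpreted as millimetres (dental-scanner convention);
    no unit conversion is attempted.  The facet soup is returned exactly as
    stored: binary STL yields three vertices per facet.

    Raises
    ------
    MeshIOError
        If the file is missing, truncated or not parseable as STL.
    """
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"STL file not found: {path}")
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted exception types
        raise MeshIOError(f"cannot parse STL file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshIOError(f"STL file {path} contains no triangles")
    if not np.isfinite(mesh.vertices).all():
        raise MeshIOError(f"STL file {path} contains non-finite coordinates")
    mesh.metadata["provenance"] = str(path)
    return mesh


def write_stl(mesh: trimesh.Trimesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` to ``path`` as binary or ASCII STL."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    if mesh is None or len(mesh.faces) == 0:
        raise MeshIOError("refusing to write an empty mesh")
    path = Path(path)
    if dialect == "binary":
        data = mesh.export(file_type="stl")
        path.write_bytes(data)
    else:
        text = mesh.export(file_type="stl_ascii")
        path.write_text(text)


@dataclasses.dataclass
class LandmarkSet:
    """The four named reference points of an appliance, in millimetres.

    ``ip``  incisive papilla (anterior midline point of the base plate),
    ``q1``/``q2``  tuber-maxilla points (posterior-lateral), and
    ``end``  tip of the velopharyngeal extension.
    """

    ip: np.ndarray
    q1: np.ndarray
    q2: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        for name in ("ip", "q1", "q2", "end"):
            value = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if value.shape != (3,) or not np.isfinite(value).all():
                raise MeshIOError(
                    f"landmark {name.upper()} must be a finite 3-vector, got {value!r}"
                )
            setattr(self, name, value)

    def points(self) -> np.ndarray:
        """All four landmarks stacked as a (4, 3) array in IP, Q1, Q2, END order."""
        return np.stack([self.ip, self.q1, self.q2, self.end])

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        """Return a copy moved by a 4x4 homogeneous transform."""
        matrix = np.asarray(matrix, dtype=float)
        pts = self.points() @ matrix[:3, :3].T + matrix[:3, 3]
        return LandmarkSet(*pts)

    def to_dict(self) -> dict:
        return {
            "IP": self.ip.tolist(),
            "Q1": self.q1.tolist(),
            "Q2": self.q2.tolist(),
            "END": self.end.tolist(),
        }


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file with keys IP, Q1, Q2, END (each ``[x, y, z]`` mm).

    Unknown extra keys are ignored with a logged warning.  Missing landmarks or
    non-numeric coordinates raise :class:`MeshIOError` naming the offender.
    """
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"landmark file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MeshIOError(f"landmark file {path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise MeshIOError(f"landmark file {path} must contain a JSON object")

    missing = [name for name in LANDMARK_NAMES if name not in payload]
    if missing:
        raise MeshIOError(
            f"landmark file {path} is missing required landmark(s): {', '.join(missing)}"
        )
    extra = sorted(set(payload) - set(LANDMARK_NAMES))
    if extra:
        log.warning("landmark file %s: ignoring extra keys %s", path, extra)

    coords = {}
    for name in LANDMARK_NAMES:
        value = payload[name]
        try:
            vec = np.asarray(value, dtype=float).reshape(3)
        except (TypeError, ValueError) as exc:
            raise MeshIOError(
                f"landmark {name} in {path} is not a numeric 3-vector: {value!r}"
            ) from exc
        if not np.isfinite(vec).all():
            raise MeshIOError(f"landmark {name} in {path} has non-finite coordinates")
        coords[name] = vec
    return LandmarkSet(coords["IP"], coords["Q1"], coords["Q2"], coords["END"])


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.to_dict(), indent=2) + "\n")


@dataclasses.dataclass
class MeasurementRecord:
    """The exported 32-value morphometric record of one appliance.

    Per section S0..S4: effective length EL (mm), sagittal length SL (mm),
    sectional area A (mm^2), width W (mm), thickness T (mm).  The tip section
    S5 carries only EL and SL.  In addition the effective-extension volume
    V_eff (mm^3) and the four skeleton turn angles alpha_1..alpha_4 (degrees).
    Missing stages are represented as NaN and exported as "NA" (CSV) or null
    (JSON).
    """

    values: dict = dataclasses.field(default_factory=dict)
    source_mesh: str = ""
    landmark_file: str = ""

    def __post_init__(self):
        clean = {name: math.nan for name in RECORD_COLUMNS}
        for key, val in dict(self.values).items():
            if key not in clean:
                raise MeshIOError(f"unknown measurement name {key!r}")
            clean[key] = math.nan if val is None else float(val)
        self.values = clean

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_array(self) -> np.ndarray:
        """The 32 values in fixed column order (NaN where missing)."""
        return np.array([self.values[c] for c in RECORD_COLUMNS])

    def is_populated(self, key: str) -> bool:
        return math.isfinite(self.values[key])

    def validate(self) -> None:
        """Check record invariants; raise :class:`MeshIOError` on violation."""
        assert len(RECORD_COLUMNS) == 32
        for key, val in self.values.items():
            if not math.isfinite(val):
                continue
            if key.startswith("alpha"):
                if not (0.0 <= val <= 180.0):
                    raise MeshIOError(f"{key}={val} outside [0, 180] degrees")
            elif val < 0:
                raise MeshIOError(f"{key}={val} is negative")
        el1 = self.values["EL_1"]
        if math.isfinite(el1) and abs(el1) > 1e-6:
            raise MeshIOError(f"EL_1 must be 0 when populated, got {el1}")

    def to_row(self) -> dict:
        row = {
            "source_mesh": self.source_mesh,
            "landmark_file": self.landmark_file,
            "tool_version": __version__,
        }
        row.update({c: self.values[c] for c in RECORD_COLUMNS})
        return row


def write_record(record: MeasurementRecord, path, format: str = "csv") -> None:
    """Export a measurement record as CSV or JSON.

    The CSV layout is one header row plus one data row: three metadata columns
    (source mesh, landmark file, tool version) followed by exactly the 32
    measurement columns in :data:`RECORD_COLUMNS` order.  Missing values are
    written as ``NA`` (CSV) or ``null`` (JSON).  A record failing its
    invariants is refused, mirroring the original tool's empty-export guard.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"unknown record format {format!r}")
    record.validate()
    n_missing = sum(not record.is_populated(c) for c in RECORD_COLUMNS)
    if n_missing == len(RECORD_COLUMNS):
        raise MeshIOError("refusing to export an entirely empty record")
    if n_missing:
        log.warning("record has %d missing value(s); exporting NA", n_missing)

    path = Path(path)
    row = record.to_row()
    if format == "csv":
        frame = pd.DataFrame([row], columns=list(META_COLUMNS) + list(RECORD_COLUMNS))
        frame.to_csv(path, index=False, na_rep="NA", float_format="%.9g")
    else:
        payload = {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in row.items()}
        path.write_text(json.dumps(payload, indent=2) + "\n")


def read_record(path, format: str | None = None) -> MeasurementRecord:
    """Read back a record written by :func:`write_record`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        frame = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
        if len(frame) != 1:
            raise MeshIOError(f"record file {path} must contain exactly one data row")
        row = frame.iloc[0].to_dict()
    else:
        row = json.loads(path.read_text())
    values = {c: row.get(c, math.nan) for c in RECORD_COLUMNS}
    values = {k: (math.nan if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)) for k, v in values.items()}
    return MeasurementRecord(
        values=values,
        source_mesh=str(row.get("source_mesh", "")),
        landmark_file=str(row.get("landmark_file", "")),
    )
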