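"""Mesh and landmark I/O.

Reads triangle meshes from VRML 2.0 (``.wrl``), PLY and OBJ files, writes
PLY and VRML, and handles the open landmark container (``.3dl.json``) plus
plain landmark coordinate tables (CSV / XLSX, wide format: one row per
item, columns x1, y1, z1, ...).

The VRML support is deliberately narrow: only the ``Coordinate.point`` and
``coordIndex`` fields of ``IndexedFaceSet`` nodes are interpreted;
materials, textures and transforms are ignored.  Polygonal faces are
triangulated by a fan from their first vertex.  This covers the geometry
that surface scanners emit and is all the downstream pipeline needs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be interpreted."""


class LandmarkFormatError(ValueError):
    """Raised when a landmark container or table is malformed."""


@dataclass
class TriangleMesh:
    """An indexed triangle surface, coordinates in model units (mm)."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bbox_diagonal(self) -> float:
        if self.n_vertices == 0:
            return 0.0
        return float(
            np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0))
        )

    def validate(self) -> "TriangleMesh":
        """Check structural invariants of an analyzable model.

        Raises :class:`MeshFormatError` on violation and returns ``self``
        for chaining.
        """
        if self.n_vertices < 4 or self.n_faces < 4:
            raise MeshFormatError(
                f"mesh too small to analyze: {self.n_vertices} vertices, "
                f"{self.n_faces} faces (need >= 4 of each)"
            )
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= self.n_vertices
        ):
            raise MeshFormatError("face index out of range")
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            raise MeshFormatError(
                f"{int(degenerate.sum())} faces with repeated vertex indices"
            )
        if not np.isfinite(self.vertices).all():
            raise MeshFormatError("non-finite vertex coordinates")
        return self

    def transformed(
        self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None
    ) -> "TriangleMesh":
        """Return a rigidly moved copy: ``v -> v @ R.T + t``."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriangleMesh(v, self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


@dataclass
class GridConfig:
    """Semi-landmark grid resolution: L latitudes x M landmarks per latitude.

    Each grid point carries two semi-landmarks (one per artifact face), so
    the total landmark count is ``2 * L * M``.
    """

    latitudes: int
    per_latitude: int

    def __post_init__(self) -> None:
        if self.latitudes < 2 or self.per_latitude < 2:
            raise ValueError("grid needs at least 2 latitudes and 2 points per latitude")

    @property
    def n_landmarks(self) -> int:
        return 2 * self.latitudes * self.per_latitude


@dataclass
class LandmarkRecord:
    """One item's landmark set, optionally with its source mesh embedded."""

    name: str
    coordinates: np.ndarray  # (k, 3) float, mm
    grid: GridConfig | None = None  # None = ungridded (e.g. table import)
    mesh: TriangleMesh | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.grid is not None and len(self.coordinates) != self.grid.n_landmarks:
            raise LandmarkFormatError(
                f"{self.name}: {len(self.coordinates)} coordinates but grid "
                f"{self.grid.latitudes}x{self.grid.per_latitude} implies "
                f"{self.grid.n_landmarks}"
            )
        if not np.isfinite(self.coordinates).all():
            raise LandmarkFormatError(f"{self.name}: non-finite landmark coordinates")

    @property
    def n_landmarks(self) -> int:
        return len(self.coordinates)


# ---------------------------------------------------------------------------
# mesh reading / writing

_NUMBER = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


def _vrml_blocks(text: str, keyword: str) -> list[str]:
    """Extract the bracketed value lists following ``keyword`` tokens."""
    blocks = []
    for match in re.finditer(rf"\b{keyword}\b", text):
        start = text.find("[", match.end())
        if start < 0:
            raise MeshFormatError(f"VRML: '{keyword}' without an opening bracket")
        end = text.find("]", start)
        if end < 0:
            raise MeshFormatError(f"VRML: unterminated '{keyword}' list")
        blocks.append(text[start + 1 : end])
    return blocks


def _triangulate_fan(polygon: Sequence[int]) -> list[tuple[int, int, int]]:
    return [(polygon[0], polygon[i], polygon[i + 1]) for i in range(1, len(polygon) - 1)]


def read_vrml(path: str | Path) -> TriangleMesh:
    """Parse the IndexedFaceSet geometry of a VRML 2.0 file.

    All IndexedFaceSet shapes in the file are merged into one mesh;
    polygonal faces are fan-triangulated.
    """
    text = Path(path).read_text()
    if "IndexedFaceSet" not in text:
        raise MeshFormatError(f"{path}: no IndexedFaceSet node found")
    # strip comments
    text = re.sub(r"#.*", "", text)
    point_blocks = _vrml_blocks(text, "point")
    index_blocks = _vrml_blocks(text, "coordIndex")
    if not point_blocks or not index_blocks:
        raise MeshFormatError(
            f"{path}: IndexedFaceSet without 'point' or 'coordIndex' list"
        )
    if len(point_blocks) != len(index_blocks):
        raise MeshFormatError(
            f"{path}: {len(point_blocks)} coordinate lists vs "
            f"{len(index_blocks)} coordIndex lists"
        )
    all_vertices: list[np.ndarray] = []
    all_faces: list[np.ndarray] = []
    offset = 0
    for points_text, index_text in zip(point_blocks, index_blocks):
        values = [float(tok) for tok in _NUMBER.findall(points_text)]
        if len(values) % 3:
            raise MeshFormatError(
                f"{path}: coordinate list length {len(values)} is not a multiple of 3"
            )
        vertices = np.array(values, dtype=float).reshape(-1, 3)
        indices = [int(float(tok)) for tok in _NUMBER.findall(index_text)]
        faces: list[tuple[int, int, int]] = []
        polygon: list[int] = []
        for idx in indices:
            if idx == -1:
                if len(polygon) >= 3:
                    faces.extend(_triangulate_fan(polygon))
                polygon = []
            else:
                polygon.append(idx)
        if len(polygon) >= 3:  # final face may lack the -1 terminator
            faces.extend(_triangulate_fan(polygon))
        if not faces:
            continue
        all_vertices.append(vertices)
        all_faces.append(np.asarray(faces, dtype=np.int64) + offset)
        offset += len(vertices)
    if not all_faces:
        raise MeshFormatError(f"{path}: no faces")
    return TriangleMesh(np.vstack(all_vertices), np.vstack(all_faces))


def write_vrml(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a minimal VRML 2.0 file with one IndexedFaceSet."""
    lines = ["#VRML V2.0 utf8", "Shape {", "  geometry IndexedFaceSet {",
             "    coord Coordinate {", "      point ["]
    lines.extend(
        f"        {float(x)!r} {float(y)!r} {float(z)!r}," for x, y, z in mesh.vertices
    )
    lines += ["      ]", "    }", "    coordIndex ["]
    lines.extend(f"      {a} {b} {c} -1," for a, b, c in mesh.faces)
    lines += ["    ]", "  }", "}", ""]
    Path(path).write_text("\n".join(lines))


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read a triangle mesh (VRML 2.0 / PLY / OBJ, dispatched by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".wrl":
        mesh = read_vrml(path)
    elif suffix in (".ply", ".obj"):
        try:
            tm = trimesh.load(str(path), force="mesh", process=False)
        except Exception as exc:  # noqa: BLE001 - surface loader failures uniformly
            raise MeshFormatError(f"{path}: {exc}") from exc
        if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
            raise MeshFormatError(f"{path}: no faces")
        mesh = TriangleMesh.from_trimesh(tm)
    else:
        raise MeshFormatError(f"{path}: unsupported mesh format '{suffix}'")
    return mesh.validate()


def write_ply(mesh: TriangleMesh, path: str | Path) -> None:
    """Write an ascii PLY file with double-precision vertex coordinates."""
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x", "property double y", "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines.extend(
        f"{float(x)!r} {float(y)!r} {float(z)!r}" for x, y, z in mesh.vertices
    )
    lines.extend(f"3 {a} {b} {c}" for a, b, c in mesh.faces)
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as ascii PLY or VRML, dispatched by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".wrl":
        write_vrml(mesh, path)
    elif suffix == ".ply":
        write_ply(mesh, path)
    else:
        raise MeshFormatError(f"{path}: unsupported mesh output format '{suffix}'")


# ---------------------------------------------------------------------------
# mesh geometry

def face_geometry(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-face unit normals, per-face areas, and the surface centroid.

    Zero-area faces get a zero normal and zero weight.  The surface
    centroid is the area-weighted mean of face centroids — robust to
    non-uniform scanner tessellation, unlike a plain vertex mean.
    """
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    if len(tri) == 0:
        raise MeshFormatError("mesh has no faces")
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    doubled = np.linalg.norm(cross, axis=1)
    areas = 0.5 * doubled
    normals = np.zeros_like(cross)
    ok = doubled > 0
    if not ok.any():
        raise MeshFormatError("all faces are degenerate")
    normals[ok] = cross[ok] / doubled[ok, None]
    centroid = np.average(tri.mean(axis=1), axis=0, weights=areas)
    return normals, areas, centroid


def surface_centroid(mesh: TriangleMesh) -> np.ndarray:
    return face_geometry(mesh)[2]


# ---------------------------------------------------------------------------
# landmark containers (.3dl.json)

_FORMAT_TAG = "3dl-json"


def write_landmarks(record: LandmarkRecord, path: str | Path) -> None:
    """Serialize a landmark record to the open JSON container.

    Floats are written with full ``repr`` precision, so the coordinate
    round-trip is exact.
    """
    doc: dict = {
        "format": _FORMAT_TAG,
        "version": 1,
        "item": record.name,
        "grid": (
            None
            if record.grid is None
            else {
                "latitudes": record.grid.latitudes,
                "per_latitude": record.grid.per_latitude,
            }
        ),
        "landmarks": record.coordinates.tolist(),
        "flags": list(record.flags),
    }
    if record.mesh is not None:
        doc["mesh"] = {
            "vertices": record.mesh.vertices.tolist(),
            "faces": record.mesh.faces.tolist(),
        }
    Path(path).write_text(json.dumps(doc))


def read_landmarks(path: str | Path) -> LandmarkRecord:
    """Read a ``.3dl.json`` landmark container."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkFormatError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("format") != _FORMAT_TAG:
        raise LandmarkFormatError(
            f"{path}: missing or wrong format tag (expected '{_FORMAT_TAG}')"
        )
    grid = None
    if doc.get("grid") is not None:
        grid = GridConfig(doc["grid"]["latitudes"], doc["grid"]["per_latitude"])
    mesh = None
    if "mesh" in doc:
        mesh = TriangleMesh(
            np.asarray(doc["mesh"]["vertices"], dtype=float),
            np.asarray(doc["mesh"]["faces"], dtype=np.int64),
        )
    return LandmarkRecord(
        name=doc.get("item", path.stem),
        coordinates=np.asarray(doc["landmarks"], dtype=float),
        grid=grid,
        mesh=mesh,
        flags=list(doc.get("flags", [])),
    )


# ---------------------------------------------------------------------------
# landmark coordinate tables (CSV / XLSX, wide format)

def _records_from_frame(frame: pd.DataFrame, names: list[str]) -> list[LandmarkRecord]:
    values = frame.to_numpy(dtype=float)
    if values.shape[1] % 3:
        raise LandmarkFormatError(
            f"table has {values.shape[1]} numeric columns, not a multiple of 3"
        )
    counts = (~np.isnan(values)).sum(axis=1)
    if len(set(counts.tolist())) > 1:
        offenders = [
            f"{name} ({int(c) // 3} landmarks)"
            for name, c in zip(names, counts)
            if c != counts.max()
        ]
        raise LandmarkFormatError(
            "inconsistent coordinate counts across items: " + ", ".join(offenders)
        )
    if np.isnan(values).any():
        raise LandmarkFormatError("missing values in landmark table")
    return [
        LandmarkRecord(name=name, coordinates=row.reshape(-1, 3))
        for name, row in zip(names, values)
    ]


def _split_names(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    first = frame.iloc[:, 0]
    if first.dtype == object and not first.map(_is_number).all():
        return frame.iloc[:, 1:], [str(v) for v in first]
    return frame, [f"item{i + 1:03d}" for i in range(len(frame))]


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def read_landmark_table(path: str | Path) -> list[LandmarkRecord]:
    """Import a wide-format landmark table (CSV or first XLSX worksheet).

    One row per item; columns ``x1, y1, z1, x2, ...``.  A header row and a
    leading item-name column are both optional and auto-detected.  Imported
    records are "ungridded": no grid configuration is attached.
    """
    path = Path(path)
    reader = pd.read_excel if path.suffix.lower() in (".xlsx", ".xls") else pd.read_csv
    raw = reader(path, header=None)
    # header detection: first row entirely non-numeric apart from the name column
    head = raw.iloc[0, 1:] if raw.shape[1] > 1 else raw.iloc[0, :]
    if not head.map(_is_number).any():
        raw = raw.iloc[1:].reset_index(drop=True)
    frame, names = _split_names(raw)
    return _records_from_frame(frame, names)


def write_landmark_table(records: Sequence[LandmarkRecord], path: str | Path) -> None:
    """Export records as a wide CSV (item name + x1,y1,z1,... columns)."""
    k = records[0].n_landmarks
    if any(r.n_landmarks != k for r in records):
        raise LandmarkFormatError("records have differing landmark counts")
    columns = [f"{axis}{i + 1}" for i in range(k) for axis in "xyz"]
    frame = pd.DataFrame(
        [r.coordinates.ravel() for r in records], columns=columns,
        index=pd.Index([r.name for r in records], name="item"),
    )
    frame.to_csv(path, float_format="%.17g")


def read_group_table(path: str | Path) -> pd.DataFrame:
    """Read a group-assignment CSV: columns item, attr1 [, attr2]."""
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[1] < 2:
        raise LandmarkFormatError(
            f"{path}: group table needs at least an item and one attribute column"
        )
    return frame.set_index(frame.columns[0])
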