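"""Read and write shape geometry and sample sheets.

Supported geometry formats are ASCII PLY, OFF, ASCII STL and CSV-xyz
(one comma-separated point per row, optional header). Coordinates are
always interpreted as millimetres; no unit inference is attempted.
Sample sheets are CSV files with columns
``sample_id, subject_id, side, sex, age``.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ShapeSample",
    "ShapeIOError",
    "read_shape",
    "write_shape",
    "read_sample_sheet",
    "write_sample_sheet",
]

_SIDES = {"L", "R"}
_SEXES = {"F", "M", "unknown"}


class ShapeIOError(ValueError):
    """Malformed geometry file or sample sheet."""


@dataclasses.dataclass
class ShapeSample:
    """One bone instance: identity, metadata and geometry.

    ``points`` is an (n, 3) float array in millimetres. ``faces`` is an
    optional (t, 3) integer array of triangle indices. ``mirrored`` records
    whether the geometry has been reflected (triangle winding reversed).
    """

    points: np.ndarray
    faces: Optional[np.ndarray] = None
    sample_id: str = ""
    subject_id: str = ""
    side: Optional[str] = None
    sex: str = "unknown"
    age: Optional[float] = None
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ShapeIOError(
                f"points must be an (n, 3) array, got shape {self.points.shape}")
        if self.points.shape[0] < 4:
            raise ShapeIOError(
                f"a shape needs at least 4 points, got {self.points.shape[0]}")
        if not np.all(np.isfinite(self.points)):
            raise ShapeIOError("points contain non-finite values")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=int)
            if self.faces.ndim != 2 or self.faces.shape[1] != 3:
                raise ShapeIOError("faces must be a (t, 3) index array")
            if self.faces.size and (self.faces.min() < 0
                                    or self.faces.max() >= len(self.points)):
                raise ShapeIOError("faces index points outside the cloud")
        if self.side is not None and self.side not in _SIDES:
            raise ShapeIOError(f"side must be one of {sorted(_SIDES)}, got {self.side!r}")
        if self.sex not in _SEXES:
            raise ShapeIOError(f"sex must be one of {sorted(_SEXES)}, got {self.sex!r}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def with_geometry(self, points, faces=None, **updates) -> "ShapeSample":
        """Copy of this sample with replaced geometry (metadata kept)."""
        kw = dict(sample_id=self.sample_id, subject_id=self.subject_id,
                  side=self.side, sex=self.sex, age=self.age,
                  mirrored=self.mirrored)
        kw.update(updates)
        return ShapeSample(points=points, faces=faces, **kw)


# ---------------------------------------------------------------------------
# geometry readers


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = path.suffix.lower().lstrip(".")
    if ext in {"ply", "off", "stl"}:
        return ext
    if ext in {"csv", "txt", "xyz"}:
        return "csv"
    raise ShapeIOError(f"cannot infer format from extension {path.suffix!r}")


def read_shape(path, format: Optional[str] = None) -> ShapeSample:
    """Read geometry from PLY/OFF/STL/CSV-xyz into a :class:`ShapeSample`.

    Only the geometry fields are populated; metadata comes from the sample
    sheet. Raises :class:`ShapeIOError` naming the offending line on
    malformed input and on empty geometry.
    """
    path = Path(path)
    if not path.exists():
        raise ShapeIOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    reader = {"ply": _read_ply, "off": _read_off,
              "stl": _read_stl, "csv": _read_csv_xyz}.get(fmt)
    if reader is None:
        raise ShapeIOError(f"unsupported format {fmt!r}")
    points, faces = reader(path)
    if len(points) == 0:
        raise ShapeIOError(f"{path}: empty geometry")
    return ShapeSample(points=points, faces=faces)


def _floats(tokens, path, lineno, n):
    try:
        vals = [float(t) for t in tokens[:n]]
    except ValueError as exc:
        raise ShapeIOError(f"{path}:{lineno}: expected numbers, got {tokens!r}") from exc
    if len(vals) < n:
        raise ShapeIOError(f"{path}:{lineno}: expected {n} values, got {len(vals)}")
    return vals


def _read_ply(path: Path):
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ShapeIOError(f"{path}:1: not a PLY file (missing 'ply' magic)")
    n_vert = n_face = 0
    vert_props: list[str] = []
    in_vertex_element = False
    i = 1
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise ShapeIOError(f"{path}:{i}: only ASCII PLY is supported")
        elif tok[0] == "element":
            in_vertex_element = tok[1] == "vertex"
            if tok[1] == "vertex":
                n_vert = int(tok[2])
            elif tok[1] == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and in_vertex_element and tok[1] != "list":
            vert_props.append(tok[-1])
        elif tok[0] == "end_header":
            break
    else:
        raise ShapeIOError(f"{path}: header never terminated with end_header")
    try:
        ix, iy, iz = (vert_props.index(ax) for ax in "xyz")
    except ValueError:
        raise ShapeIOError(f"{path}: vertex element lacks x/y/z properties")
    body = lines[i:]
    if len(body) < n_vert + n_face:
        raise ShapeIOError(
            f"{path}: expected {n_vert} vertices + {n_face} faces, "
            f"found {len(body)} body lines")
    points = np.empty((n_vert, 3))
    for v in range(n_vert):
        vals = _floats(body[v].split(), path, i + 1 + v, len(vert_props))
        points[v] = vals[ix], vals[iy], vals[iz]
    faces = None
    if n_face:
        faces = np.empty((n_face, 3), dtype=int)
        for f in range(n_face):
            lineno = i + 1 + n_vert + f
            tok = body[n_vert + f].split()
            if not tok or tok[0] != "3":
                raise ShapeIOError(f"{path}:{lineno}: only triangular faces supported")
            faces[f] = [int(t) for t in tok[1:4]]
    return points, faces


def _read_off(path: Path):
    raw = path.read_text().splitlines()
    lines = [(n, l.strip()) for n, l in enumerate(raw, start=1)
             if l.strip() and not l.strip().startswith("#")]
    if not lines or not lines[0][1].startswith("OFF"):
        raise ShapeIOError(f"{path}:1: not an OFF file (missing 'OFF' magic)")
    first = lines[0][1][3:].split()
    rest = lines[1:]
    if first:  # counts on the magic line
        counts, ln = first, lines[0][0]
    else:
        if not rest:
            raise ShapeIOError(f"{path}: missing count line")
        (ln, cl), rest = rest[0], rest[1:]
        counts = cl.split()
    if len(counts) < 2:
        raise ShapeIOError(f"{path}:{ln}: expected 'n_vertices n_faces n_edges'")
    n_vert, n_face = int(counts[0]), int(counts[1])
    if len(rest) < n_vert + n_face:
        raise ShapeIOError(f"{path}: truncated: {n_vert} vertices + "
                           f"{n_face} faces declared, {len(rest)} lines present")
    points = np.empty((n_vert, 3))
    for v in range(n_vert):
        ln, line = rest[v]
        points[v] = _floats(line.split(), path, ln, 3)
    faces = None
    if n_face:
        faces = np.empty((n_face, 3), dtype=int)
        for f in range(n_face):
            ln, line = rest[n_vert + f]
            tok = line.split()
            if tok[0] != "3":
                raise ShapeIOError(f"{path}:{ln}: only triangular faces supported")
            faces[f] = [int(t) for t in tok[1:4]]
    return points, faces


def _read_stl(path: Path):
    lines = path.read_text().splitlines()
    if not lines or not lines[0].lstrip().startswith("solid"):
        raise ShapeIOError(f"{path}:1: not an ASCII STL file (binary STL is "
                           "unsupported; export as ASCII)")
    verts: list[tuple] = []
    index: dict[tuple, int] = {}
    tri: list[int] = []
    faces = []
    for n, line in enumerate(lines, start=1):
        tok = line.split()
        if tok and tok[0] == "vertex":
            xyz = tuple(_floats(tok[1:], path, n, 3))
            j = index.setdefault(xyz, len(verts))
            if j == len(verts):
                verts.append(xyz)
            tri.append(j)
            if len(tri) == 3:
                faces.append(tri)
                tri = []
    if tri:
        raise ShapeIOError(f"{path}: facet with fewer than 3 vertices")
    if not faces:
        raise ShapeIOError(f"{path}: no facets found")
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=int)


def _read_csv_xyz(path: Path):
    rows = []
    for n, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        tok = [t for t in line.replace(",", " ").split() if t]
        try:
            rows.append([float(t) for t in tok[:3]])
        except ValueError:
            if n == 1:  # optional header row
                continue
            raise ShapeIOError(f"{path}: row {n}: non-numeric value in {tok!r}")
        if len(tok) < 3:
            raise ShapeIOError(f"{path}: row {n}: expected 3 coordinates")
    return np.asarray(rows, dtype=float).reshape(-1, 3), None


# ---------------------------------------------------------------------------
# geometry writers


def write_shape(sample_or_points, path, format: Optional[str] = None) -> Path:
    """Write geometry to PLY/OFF/STL/CSV-xyz (format inferred from suffix)."""
    path = Path(path)
    if isinstance(sample_or_points, ShapeSample):
        points, faces = sample_or_points.points, sample_or_points.faces
    else:
        points, faces = np.asarray(sample_or_points, dtype=float), None
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        _write_ply(path, points, faces)
    elif fmt == "off":
        _write_off(path, points, faces)
    elif fmt == "stl":
        if faces is None:
            raise ShapeIOError("STL requires faces; use PLY/CSV for point clouds")
        _write_stl(path, points, faces)
    elif fmt == "csv":
        _write_csv_xyz(path, points)
    else:
        raise ShapeIOError(f"unsupported format {fmt!r}")
    return path


def _fmt_xyz(p):
    return f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"


def _write_ply(path, points, faces):
    n_face = 0 if faces is None else len(faces)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if n_face:
            fh.write(f"element face {n_face}\n")
            fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for p in points:
            fh.write(_fmt_xyz(p) + "\n")
        if n_face:
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _write_off(path, points, faces):
    n_face = 0 if faces is None else len(faces)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(points)} {n_face} 0\n")
        for p in points:
            fh.write(_fmt_xyz(p) + "\n")
        if n_face:
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _write_stl(path, points, faces):
    with open(path, "w") as fh:
        fh.write("solid shape\n")
        for f in faces:
            a, b, c = points[f[0]], points[f[1]], points[f[2]]
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            fh.write(f"  facet normal {_fmt_xyz(n)}\n    outer loop\n")
            for p in (a, b, c):
                fh.write(f"      vertex {_fmt_xyz(p)}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid shape\n")


def _write_csv_xyz(path, points):
    with open(path, "w") as fh:
        fh.write("x,y,z\n")
        for p in points:
            fh.write(f"{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}\n")


# ---------------------------------------------------------------------------
# sample sheets

_REQUIRED_COLUMNS = ["sample_id", "subject_id", "side", "sex", "age"]


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet.

    Enforces: required columns present, unique ``sample_id``, side values in
    {L, R}, and at most one sample per (subject, side). Missing ages are kept
    as NaN so downstream covariate analyses can exclude them explicitly.
    """
    path = Path(path)
    sheet = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in sheet.columns]
    if missing:
        raise ShapeIOError(f"{path}: missing required columns {missing}")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if not dup.empty:
        raise ShapeIOError(f"{path}: duplicate sample_id values: {sorted(set(dup))}")
    bad_side = sorted(set(sheet["side"]) - _SIDES)
    if bad_side:
        raise ShapeIOError(f"{path}: side values outside {{L, R}}: {bad_side}")
    dup_pair = sheet[sheet.duplicated(subset=["subject_id", "side"], keep=False)]
    if not dup_pair.empty:
        pairs = sorted({(r.subject_id, r.side) for r in dup_pair.itertuples()})
        raise ShapeIOError(f"{path}: subject with two same-side entries: {pairs}")
    sheet["sex"] = sheet["sex"].fillna("unknown").astype(str)
    bad_sex = sorted(set(sheet["sex"]) - _SEXES)
    if bad_sex:
        raise ShapeIOError(f"{path}: sex values outside {{F, M, unknown}}: {bad_sex}")
    sheet["age"] = pd.to_numeric(sheet["age"], errors="coerce")
    return sheet


def write_sample_sheet(records, path) -> Path:
    """Write a sample sheet CSV from an iterable of record dicts/rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(records, columns=_REQUIRED_COLUMNS)
    frame.to_csv(path, index=False)
    return path
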