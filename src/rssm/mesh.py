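"""Triangle-mesh data model and surface-file I/O.

The package's unit of data is one triangulated bone surface per subject,
with coordinates in millimetres.  Vertex order is semantic: downstream
correspondence identifies vertex ``i`` across subjects positionally, so
readers and writers must never reorder vertices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh

__all__ = ["TriangleMesh", "MeshValidationError", "read_mesh", "write_mesh", "validate_mesh"]

_FORMATS = ("ply", "stl", "obj")


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class TriangleMesh:
    """A triangulated surface: ``vertices`` (V, 3) float64 mm, ``faces`` (F, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (F, 3) array")

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    @property
    def face_count(self) -> int:
        return len(self.faces)

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            self.name if name is None else name)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity, new coordinates."""
        return TriangleMesh(np.asarray(vertices, float), self.faces.copy(), self.name)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (E, 2) index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.vertex_count - len(self.edges()) + self.face_count


def validate_mesh(mesh: TriangleMesh) -> list[str]:
    """Return a list of invariant violations (empty list = valid mesh).

    Checks, in order: finite coordinates, minimum size (V >= 4, F >= 4),
    face indices in range, and degenerate faces (repeated indices).
    Reporting is deterministic and names the offending element.
    """
    report: list[str] = []
    bad = ~np.isfinite(mesh.vertices).all(axis=1)
    for i in np.flatnonzero(bad):
        report.append(f"non-finite coordinate at vertex {i}")
    if mesh.vertex_count < 4:
        report.append(f"vertex_count {mesh.vertex_count} < 4")
    if mesh.face_count < 4:
        report.append(f"face_count {mesh.face_count} < 4")
    out = (mesh.faces < 0) | (mesh.faces >= mesh.vertex_count)
    for i in np.flatnonzero(out.any(axis=1)):
        report.append(f"face {i} has vertex index out of range")
    f = mesh.faces
    degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    for i in np.flatnonzero(degen):
        report.append(f"degenerate face {i} (repeated vertex index)")
    return report


def _require_valid(mesh: TriangleMesh) -> None:
    report = validate_mesh(mesh)
    if report:
        raise MeshValidationError("; ".join(report))


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None and fmt != "auto":
        f = fmt.lower()
        if f not in _FORMATS:
            raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
        return f
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext not in _FORMATS:
        raise ValueError(f"cannot infer format from extension {ext!r}")
    return ext


def _merge_exact_duplicates(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices equal to the bit; first occurrence keeps its position.

    STL stores each facet's corners independently, so an indexed mesh must be
    rebuilt.  Exact (not tolerance-based) merging keeps round-trips
    deterministic.
    """
    seen: dict[bytes, int] = {}
    index_map = np.empty(len(vertices), dtype=np.int64)
    keep: list[int] = []
    for i, v in enumerate(vertices):
        key = v.tobytes()
        j = seen.get(key)
        if j is None:
            j = len(keep)
            seen[key] = j
            keep.append(i)
        index_map[i] = j
    return vertices[keep], index_map[faces]


def read_mesh(path: str, fmt: str | None = "auto") -> TriangleMesh:
    """Read a PLY, STL or OBJ surface into a :class:`TriangleMesh`.

    Vertex order is preserved for indexed formats (PLY, OBJ).  STL facets
    are merged into an indexed mesh by exact coordinate equality.  The
    result is validated; a structurally invalid file raises
    :class:`MeshValidationError` naming the offending element.
    """
    f = _detect_format(path, fmt)
    if not os.path.exists(path):
        raise IOError(f"mesh file not found: {path}")
    try:
        tm = _trimesh.load(path, file_type=f, process=False)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise IOError(f"could not read {path} as {f}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh):
        raise IOError(f"{path} does not contain a single triangulated surface")
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if f == "stl":
        vertices, faces = _merge_exact_duplicates(vertices, faces)
    mesh = TriangleMesh(vertices, faces, name=os.path.splitext(os.path.basename(path))[0])
    _require_valid(mesh)
    return mesh


def _write_ply(mesh: TriangleMesh, path: str, binary: bool) -> None:
    # float64 coordinates so write->read is the identity (trimesh's own
    # exporter downcasts to float32).
    v, f = mesh.vertices, mesh.faces
    enc = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {enc} 1.0\n"
        f"element vertex {len(v)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(f)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(v.astype("<f8").tobytes())
            rec = np.empty(len(f), dtype=[("n", "u1"), ("idx", "<i4", (3,))])
            rec["n"] = 3
            rec["idx"] = f
            fh.write(rec.tobytes())
        else:
            lines = ["%.17g %.17g %.17g" % tuple(p) for p in v]
            lines += ["3 %d %d %d" % tuple(t) for t in f]
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def write_mesh(mesh: TriangleMesh, path: str, fmt: str | None = "auto",
               binary: bool = False) -> None:
    """Write a mesh to PLY (lossless float64), STL or OBJ.

    The mesh is validated before any file is created.  PLY output uses
    ``property double`` so that ``read_mesh(write_mesh(m))`` reproduces the
    coordinates bit-exactly; ``binary=True`` selects binary little-endian.
    """
    f = _detect_format(path, fmt)
    _require_valid(mesh)
    if f == "ply":
        _write_ply(mesh, path, binary=binary)
        return
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    try:
        tm.export(path, file_type=f)
    except Exception as exc:
        raise IOError(f"could not write {path}: {exc}") from exc
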