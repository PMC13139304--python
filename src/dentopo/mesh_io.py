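"""Reading, validating and writing triangulated tooth-crown meshes.

The analysis pipeline operates on single lower-molar crowns stored as
triangle meshes (PLY, OBJ or OFF).  A :class:`ToothMesh` is a thin,
validated container around vertex and face arrays; the convention for an
occlusally oriented crown is +z toward the crown apex, +x mesial and
+y buccal, so the lingual view is the projection onto the x-z plane seen
from -y.

File parsing and serialisation are delegated to :mod:`trimesh`; this module
only adds the validation contract (in-range indices, non-degenerate faces)
and keeps I/O lossless (no geometric welding, no processing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

_FORMATS = ("ply", "obj", "off")


class MeshFormatError(ValueError):
    """File could not be parsed as the declared mesh format."""


class MeshValidationError(ValueError):
    """Mesh violates a ToothMesh invariant (indices, degeneracy, emptiness)."""


@dataclass(frozen=True)
class ToothMesh:
    """A validated triangulated crown surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates; units arbitrary but consistent (typically mm).
    faces : (m, 3) int array
        Triangles as triples of 0-based vertex indices.
    orientation_flag : bool
        True when the mesh is known to be occlusally oriented
        (+z apex, +x mesial, +y buccal).
    """

    vertices: np.ndarray
    faces: np.ndarray
    orientation_flag: bool = False
    _trimesh_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        validate_mesh(v, f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        """The geometry as a trimesh object (cached; do not mutate)."""
        tm = self._trimesh_cache.get("tm")
        if tm is None:
            tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
            self._trimesh_cache["tm"] = tm
        return tm

    def with_vertices(self, vertices: np.ndarray) -> "ToothMesh":
        """Same topology, new vertex positions."""
        return replace(self, vertices=np.asarray(vertices, float), _trimesh_cache={})

    def oriented(self, flag: bool = True) -> "ToothMesh":
        return replace(self, orientation_flag=flag, _trimesh_cache={})


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    return 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )


def validate_mesh(vertices: np.ndarray, faces: np.ndarray) -> None:
    """Raise :class:`MeshValidationError` unless (vertices, faces) form a
    valid ToothMesh: non-empty, in-range distinct indices, no zero-area face.
    """
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise MeshValidationError(f"vertices must be (n, 3), got {vertices.shape}")
    if faces.size == 0:
        raise MeshValidationError("mesh has zero faces")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshValidationError(f"faces must be (m, 3), got {faces.shape}")
    if not np.isfinite(vertices).all():
        raise MeshValidationError("vertices contain non-finite coordinates")
    bad = (faces < 0) | (faces >= len(vertices))
    if bad.any():
        i = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise MeshValidationError(
            f"face {i} references out-of-range vertex index {faces[i].tolist()} "
            f"(n_vertices={len(vertices)})"
        )
    repeated = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    if repeated.any():
        i = int(np.argwhere(repeated)[0, 0])
        raise MeshValidationError(f"face {i} repeats a vertex index: {faces[i].tolist()}")
    degen = face_areas(vertices, faces) <= 0.0
    if degen.any():
        i = int(np.argwhere(degen)[0, 0])
        raise MeshValidationError(f"face {i} is degenerate (zero area)")


def _infer_format(path: Path, fmt: str) -> str:
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_mesh(path, fmt: str = "auto") -> ToothMesh:
    """Read a PLY/OBJ/OFF file into a validated :class:`ToothMesh`.

    No welding or processing is applied: the stored vertices and faces are
    returned as-is (after 0-based index translation where the format needs
    it, which trimesh performs at parse time).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    try:
        tm = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises heterogeneous types
        raise MeshFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if tm.faces is None or len(tm.faces) == 0:
        raise MeshValidationError(f"{path}: mesh has zero faces")
    mesh = ToothMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    log.info("read %s: %d vertices, %d faces", path, mesh.n_vertices, mesh.n_faces)
    return mesh


def write_mesh(mesh: ToothMesh, path, fmt: str = "auto"):
    """Write a ToothMesh to disk (ASCII dialect for diffability)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    tm = mesh.as_trimesh()
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        path.write_bytes(data)
    else:
        tm.export(path, file_type=fmt)
    log.info("wrote %s (%s, ascii)", path, fmt)
    return path
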