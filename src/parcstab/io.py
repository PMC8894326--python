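"""Surface and annotation I/O.

Two interchangeable on-disk representations are supported:

* FreeSurfer binary formats via :mod:`nibabel.freesurfer` — triangle geometry
  files and ``.annot`` parcellation annotations (parcel identifiers are encoded
  in the annotation label names as ``parcel_<id>`` so round-trips are lossless);
* a plain-text fallback — OFF mesh files plus one-label-per-line text files —
  convenient for fixtures and inspection.

Format is chosen by extension: ``.off`` / ``.labels.txt`` / ``.txt`` select the
text formats, ``.annot`` the FreeSurfer annotation, anything else the
FreeSurfer geometry format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import nibabel.freesurfer as nfs

from .mesh import MalformedMeshError, Parcellation, TriangleMesh

__all__ = [
    "read_surface",
    "write_surface",
    "read_labels",
    "write_labels",
    "read_parcellation",
]


def read_surface(path: str | Path, validate: bool = True) -> TriangleMesh:
    """Read a triangle mesh from an OFF file or a FreeSurfer geometry file.

    Non-manifold or open real surfaces are accepted with a warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".off":
        mesh = _read_off(path)
    else:
        coords, faces = nfs.read_geometry(str(path))
        mesh = TriangleMesh(np.asarray(coords, float), np.asarray(faces, np.int64))
    if validate:
        mesh.validate(require_closed=False)
    return mesh


def write_surface(path: str | Path, mesh: TriangleMesh) -> None:
    path = Path(path)
    if path.suffix.lower() == ".off":
        _write_off(path, mesh)
    else:
        nfs.write_geometry(str(path), mesh.vertices, mesh.faces)


def read_labels(path: str | Path, n_vertices: int | None = None) -> np.ndarray:
    """Read per-vertex parcel labels from a ``.annot`` file or a text file."""
    path = Path(path)
    if path.suffix.lower() == ".annot":
        indices, _, names = nfs.read_annot(str(path))
        ids = np.array([_id_from_name(n) for n in names], dtype=np.int64)
        labels = ids[indices]
    else:
        labels = np.loadtxt(path, dtype=np.int64, ndmin=1)
    if n_vertices is not None and len(labels) != n_vertices:
        raise ValueError(f"expected {n_vertices} labels, file has {len(labels)}")
    return labels


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    path = Path(path)
    labels = np.asarray(labels, dtype=np.int64)
    if path.suffix.lower() == ".annot":
        ids = np.unique(labels)
        names = [_name_from_id(int(i)) for i in ids]
        ctab = _color_table(len(ids))
        nfs.write_annot(str(path), np.searchsorted(ids, labels).astype(np.int32),
                        ctab, names, fill_ctab=True)
    else:
        np.savetxt(path, labels, fmt="%d")


def read_parcellation(surface_path: str | Path, labels_path: str | Path,
                      validate: bool = True) -> Parcellation:
    mesh = read_surface(surface_path, validate=validate)
    labels = read_labels(labels_path, n_vertices=mesh.vertex_count)
    return Parcellation(mesh, labels)


def _name_from_id(pid: int) -> str:
    return f"parcel_{pid}"


def _id_from_name(name: bytes | str) -> int:
    if isinstance(name, bytes):
        name = name.decode()
    if not name.startswith("parcel_"):
        raise ValueError(f"annotation label {name!r} was not written by this package "
                         "(expected 'parcel_<id>')")
    return int(name.removeprefix("parcel_"))


def _color_table(n: int) -> np.ndarray:
    # distinct RGB rows; packed annotation values must be unique and nonzero
    # (the all-black entry packs to 0, which annotation readers treat as
    # "unlabelled", so colours start at 1)
    idx = np.arange(1, n + 1, dtype=np.int64)
    ctab = np.zeros((n, 5), dtype=np.int64)
    ctab[:, 0] = idx % 256
    ctab[:, 1] = (idx // 256) % 256
    ctab[:, 2] = (idx // 65536) % 256
    return ctab


def _read_off(path: Path) -> TriangleMesh:
    tokens: list[str] = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first != "OFF":
            raise MalformedMeshError(f"{path}: not an OFF file")
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    nv, nf = int(tokens[0]), int(tokens[1])
    pos = 3
    verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise MalformedMeshError(f"{path}: face {i} has {k} vertices, only triangles supported")
        faces[i] = [int(t) for t in tokens[pos + 1:pos + 4]]
        pos += 1 + k
    return TriangleMesh(verts, faces)


def _write_off(path: Path, mesh: TriangleMesh) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.vertex_count} {mesh.face_count} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
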