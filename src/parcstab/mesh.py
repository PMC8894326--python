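"""Triangle-mesh and surface-parcellation data model.

A cortical surface is represented as a triangle mesh (vertex coordinates plus
faces) and a parcellation as a total per-vertex labelling into parcels.  The
perturbation algorithm operates purely on mesh topology: vertex adjacency,
parcel membership, and the classification of faces into *internal* faces
(all three vertices share one label) and *boundary* faces (labels differ),
which delimit parcel borders and seed region growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MalformedMeshError",
    "InvalidParcellationError",
    "TriangleMesh",
    "Parcellation",
    "FaceClassification",
    "build_vertex_adjacency",
    "classify_faces",
    "parcel_sizes",
    "check_parcel_connectivity",
]


class MalformedMeshError(ValueError):
    """A face references duplicate or out-of-range vertices, or the mesh is disconnected."""


class InvalidParcellationError(ValueError):
    """A labelling violates the parcellation contract (wrong length, empty parcel...)."""


@dataclass(frozen=True)
class TriangleMesh:
    """Closed 2-manifold triangle mesh (synthetic meshes; real surfaces may have boundaries).

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates.  Only used for I/O; the algorithms are topological.
    faces : (F, 3) int array
        0-based vertex index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        vertices = np.asarray(self.vertices, dtype=float)
        faces = np.asarray(self.faces, dtype=np.int64)
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "faces", faces)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MalformedMeshError("vertices must be a (V, 3) array")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise MalformedMeshError("faces must be a (F, 3) array")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise MalformedMeshError("face references an out-of-range vertex")
        if ((faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2])
                | (faces[:, 0] == faces[:, 2])).any():
            raise MalformedMeshError("face references a duplicate vertex")

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    @property
    def face_count(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @property
    def vertex_adjacency(self) -> list[np.ndarray]:
        # cached lazily on first access; frozen dataclass, so stash in __dict__
        cached = self.__dict__.get("_adjacency")
        if cached is None:
            cached = build_vertex_adjacency(self)
            self.__dict__["_adjacency"] = cached
        return cached

    @property
    def adjacency_sparse(self) -> csr_matrix:
        cached = self.__dict__.get("_adjacency_sparse")
        if cached is None:
            e = self.edges
            n = self.vertex_count
            data = np.ones(2 * len(e), dtype=np.int8)
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            cached = csr_matrix((data, (rows, cols)), shape=(n, n))
            self.__dict__["_adjacency_sparse"] = cached
        return cached

    def validate(self, require_closed: bool = True) -> None:
        """Check connectivity and (optionally) the closed-manifold edge condition.

        Real FreeSurfer hemisphere surfaces can have boundary edges after
        medial-wall handling; those are accepted with a warning when
        ``require_closed`` is False-tolerant (a warning, never an error).
        """
        n_comp, _ = connected_components(self.adjacency_sparse, directed=False)
        if n_comp != 1:
            raise MalformedMeshError(f"mesh adjacency graph has {n_comp} components")
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if (counts != 2).any():
            msg = f"{int((counts != 2).sum())} edges do not belong to exactly two faces"
            if require_closed:
                raise MalformedMeshError("mesh is not a closed 2-manifold: " + msg)
            warnings.warn("surface is not a closed 2-manifold: " + msg, stacklevel=2)


def build_vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """Per-vertex sorted arrays of neighbouring vertex indices.

    Two vertices are adjacent iff they share an edge of some face.
    """
    e = mesh.edges
    order = np.argsort(np.concatenate([e[:, 0], e[:, 1]]), kind="stable")
    endpoints = np.concatenate([e[:, 1], e[:, 0]])[order]
    counts = np.bincount(np.concatenate([e[:, 0], e[:, 1]]), minlength=mesh.vertex_count)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return [np.sort(endpoints[offsets[v]:offsets[v + 1]]) for v in range(mesh.vertex_count)]


@dataclass
class Parcellation:
    """Total labelling of mesh vertices into parcels.

    ``labels`` may use arbitrary integer identifiers; ``parcel_ids`` lists the
    distinct identifiers in sorted order.  Every parcel is non-empty by
    construction (identifiers are taken from the labelling itself).
    """

    mesh: TriangleMesh
    labels: np.ndarray
    parcel_ids: np.ndarray = field(init=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or len(self.labels) != self.mesh.vertex_count:
            raise InvalidParcellationError(
                f"labels must be a length-{self.mesh.vertex_count} vector, "
                f"got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidParcellationError("labels must be integers")
        self.parcel_ids = np.unique(self.labels)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def v_tot(self) -> int:
        return self.mesh.vertex_count

    @property
    def sizes(self) -> dict[int, int]:
        return parcel_sizes(self)[0]

    def dense_labels(self) -> np.ndarray:
        """Labels remapped to dense 0..P-1 following ``parcel_ids`` order."""
        return np.searchsorted(self.parcel_ids, self.labels)

    def with_labels(self, labels: np.ndarray) -> "Parcellation":
        return Parcellation(self.mesh, labels)

    def members(self, parcel_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == parcel_id)


@dataclass(frozen=True)
class FaceClassification:
    """Partition of face indices into internal and boundary faces."""

    internal_faces: np.ndarray
    boundary_faces: np.ndarray


def classify_faces(parc: Parcellation) -> FaceClassification:
    """Split faces into internal (all three vertex labels equal) and boundary faces."""
    f = parc.mesh.faces
    lab = parc.labels
    internal = (lab[f[:, 0]] == lab[f[:, 1]]) & (lab[f[:, 1]] == lab[f[:, 2]])
    idx = np.arange(len(f))
    return FaceClassification(internal_faces=idx[internal], boundary_faces=idx[~internal])


def parcel_sizes(parc: Parcellation) -> tuple[dict[int, int], int]:
    """Per-parcel vertex counts V_i and the total V_tot; sizes always sum to V_tot."""
    ids, counts = np.unique(parc.labels, return_counts=True)
    if (counts < 1).any():  # unreachable by construction; guards future mutation
        raise InvalidParcellationError("empty parcel")
    return dict(zip(ids.tolist(), counts.tolist())), parc.v_tot


def check_parcel_connectivity(parc: Parcellation) -> dict[int, bool]:
    """True per parcel iff its vertex-induced adjacency subgraph is connected.

    This is the testable proxy for parcels "without holes": region growth can
    split a donor parcel into islands, which this check detects.
    """
    adj = parc.mesh.adjacency_sparse
    dense = parc.dense_labels()
    result: dict[int, bool] = {}
    for k, pid in enumerate(parc.parcel_ids):
        members = np.flatnonzero(dense == k)
        sub = adj[members][:, members]
        n_comp, _ = connected_components(sub, directed=False)
        result[int(pid)] = bool(n_comp == 1)
    return result
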