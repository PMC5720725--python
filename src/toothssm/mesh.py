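"""Triangulated surface meshes and the geometric primitives built on them.

The model frame used throughout the package is: +x mesial, +y labial,
+z incisal (so -z is apical); units are millimetres.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidInputError, PreconditionError

# Coordinates closer than this (mm) are considered the same vertex.
MERGE_TOLERANCE = 1e-9


@dataclass
class SurfaceMesh:
    """A triangle mesh: ``vertices`` (n, 3) float64 mm, ``faces`` (m, 3) int.

    ``vertex_material`` optionally carries a per-vertex material value
    (1 = enamel, 0 = dentin); it travels with the mesh through I/O.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_material: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidInputError("vertices must be an (n, 3) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise InvalidInputError("faces must be an (m, 3) array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise InvalidInputError("face indices out of range")
        if self.vertex_material is not None:
            self.vertex_material = np.asarray(self.vertex_material, dtype=np.float64)
            if self.vertex_material.shape != (len(self.vertices),):
                raise InvalidInputError("vertex_material length must match vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        mat = None if self.vertex_material is None else self.vertex_material.copy()
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), mat)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same connectivity (and material) with replaced coordinates."""
        mat = None if self.vertex_material is None else self.vertex_material.copy()
        return SurfaceMesh(np.asarray(vertices, dtype=np.float64), self.faces.copy(), mat)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def boundary_edge_count(self) -> int:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int(np.sum(counts == 1))

    def is_closed(self) -> bool:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def median_edge_length(self) -> float:
        e = self.edges()
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        return float(np.median(d))

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalize:
            lengths = np.linalg.norm(n, axis=1, keepdims=True)
            lengths[lengths == 0] = 1.0
            n = n / lengths
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length)."""
        fn = self.face_normals(normalize=False)  # magnitude = 2 * area
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        lengths = np.linalg.norm(vn, axis=1, keepdims=True)
        lengths[lengths == 0] = 1.0
        return vn / lengths


@dataclass
class ElementAdjacency:
    """Edge-sharing neighbours per face: ``neighbors[i]`` lists face ids."""

    neighbors: list = field(default_factory=list)

    def __len__(self):
        return len(self.neighbors)

    def __getitem__(self, i):
        return self.neighbors[i]


def clean_mesh(vertices: np.ndarray, faces: np.ndarray,
               vertex_material: np.ndarray | None = None,
               tol: float = MERGE_TOLERANCE) -> SurfaceMesh:
    """Merge duplicate vertices within ``tol`` and drop degenerate faces.

    First-occurrence vertex order is preserved.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if len(vertices) == 0:
        raise InvalidInputError("mesh has no vertices")
    decimals = max(0, int(round(-np.log10(tol))))
    keys = np.round(vertices, decimals)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # remap so kept vertices keep their original relative order
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    remap = rank[inverse]
    new_faces = remap[faces] if faces.size else faces
    if new_faces.size:
        # degenerate: repeated index or (numerically) zero area
        distinct = (
            (new_faces[:, 0] != new_faces[:, 1])
            & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2])
        )
        new_faces = new_faces[distinct]
        a = new_vertices[new_faces[:, 1]] - new_vertices[new_faces[:, 0]]
        b = new_vertices[new_faces[:, 2]] - new_vertices[new_faces[:, 0]]
        areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        new_faces = new_faces[areas > 0.0]
    mat = None
    if vertex_material is not None:
        mat = np.asarray(vertex_material, dtype=np.float64)[first[order]]
    return SurfaceMesh(new_vertices, new_faces, mat)


def surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area in mm^2."""
    v = mesh.vertices
    f = mesh.faces
    if f.size == 0:
        return 0.0
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Volume (mm^3) of a closed, consistently wound mesh.

    Divergence-theorem tetrahedron sum; the absolute value is returned so
    the result is independent of global winding direction.
    """
    n_boundary = mesh.boundary_edge_count()
    if n_boundary:
        raise PreconditionError(
            f"mesh is not closed: {n_boundary} boundary edge(s); volume undefined"
        )
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))
    return float(abs(signed.sum()) / 6.0)


def signed_volume(mesh: SurfaceMesh) -> float:
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))
    return float(signed.sum() / 6.0)


def nearest_vertices(query: np.ndarray, reference: np.ndarray):
    """Exact nearest neighbour of each query point among ``reference``.

    Returns ``(indices, distances)``. Ties are broken toward the lowest
    reference index.
    """
    reference = np.asarray(reference, dtype=np.float64).reshape(-1, 3)
    query = np.asarray(query, dtype=np.float64).reshape(-1, 3)
    if len(reference) == 0:
        raise InvalidInputError("reference point set is empty")
    tree = cKDTree(reference)
    k = min(4, len(reference))
    d, i = tree.query(query, k=k)
    if k == 1:
        return np.atleast_1d(i), np.atleast_1d(d)
    d = np.atleast_2d(d)
    i = np.atleast_2d(i)
    best = np.empty(len(query), dtype=np.int64)
    bestd = d[:, 0].copy()
    for row in range(len(query)):
        tied = i[row, d[row] == d[row, 0]]
        best[row] = tied.min()
    return best, bestd


def build_adjacency(mesh: SurfaceMesh) -> ElementAdjacency:
    """Edge-sharing face adjacency. Non-manifold edges trigger a warning but
    every pairing is still recorded."""
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            edge_faces.setdefault(key, []).append(fi)
    neighbors: list[list[int]] = [[] for _ in range(mesh.n_faces)]
    nonmanifold = 0
    for key, flist in edge_faces.items():
        if len(flist) > 2:
            nonmanifold += 1
        for a in flist:
            for b in flist:
                if a != b and b not in neighbors[a]:
                    neighbors[a].append(b)
    if nonmanifold:
        warnings.warn(f"{nonmanifold} non-manifold edge(s) shared by >2 faces")
    for lst in neighbors:
        lst.sort()
    return ElementAdjacency(neighbors)


def vertex_face_incidence(mesh: SurfaceMesh) -> list[list[int]]:
    """Faces incident on each vertex."""
    inc: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for fi, face in enumerate(mesh.faces):
        for v in face:
            inc[v].append(fi)
    return inc


def submesh(mesh: SurfaceMesh, vertex_mask: np.ndarray) -> SurfaceMesh:
    """Sub-mesh of faces whose three vertices are all selected, reindexed."""
    vertex_mask = np.asarray(vertex_mask, dtype=bool)
    keep_faces = vertex_mask[mesh.faces].all(axis=1)
    faces = mesh.faces[keep_faces]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    mat = None if mesh.vertex_material is None else mesh.vertex_material[used]
    return SurfaceMesh(mesh.vertices[used], remap[faces], mat)
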