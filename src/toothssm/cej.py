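"""Binarisation and smoothing of surface material labels, and extraction
of the cemento-enamel junction (CEJ) boundary curve.

Node-valued probabilistic material I in [0, 1] is thresholded at the
mid-range value (I >= 0.5 -> enamel), mapped to elements by majority
vote, cleaned by flipping any element with two or more opposite-material
neighbours until a fixed point, and the enamel/dentin element boundary is
chained into closed loops.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .mesh import ElementAdjacency, SurfaceMesh, build_adjacency, vertex_face_incidence

__all__ = [
    "MaterialField", "CEJCurve", "binarize", "elements_from_nodes",
    "smooth_materials", "nodes_from_elements", "extract_cej",
]


@dataclass
class MaterialField:
    node_values: np.ndarray          # probabilistic I in [0, 1]
    node_binary: np.ndarray          # Ih in {0, 1}
    element_material: np.ndarray     # per-face material in {0, 1}


@dataclass
class CEJCurve:
    """Closed loops of mesh vertices separating enamel from dentin elements,
    sorted by length (mm) descending."""

    loops: list = field(default_factory=list)    # each an ordered vertex-index list
    lengths: list = field(default_factory=list)  # loop length in mm

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    def is_continuous(self) -> bool:
        """The anatomical check: exactly one unbroken loop."""
        return self.n_loops == 1

    def node_indices(self) -> np.ndarray:
        if not self.loops:
            return np.zeros(0, dtype=np.int64)
        return np.unique(np.concatenate([np.asarray(l) for l in self.loops]))


def binarize(node_values: np.ndarray) -> np.ndarray:
    """Ih = 1 iff I >= 0.5 (the mid-range threshold)."""
    node_values = np.asarray(node_values, dtype=np.float64)
    if node_values.size and (node_values.min() < 0.0 or node_values.max() > 1.0):
        raise InvalidInputError("material values must lie in [0, 1]")
    return (node_values >= 0.5).astype(np.float64)


def elements_from_nodes(mesh: SurfaceMesh, node_binary: np.ndarray) -> np.ndarray:
    """Element material by 2-of-3 majority of its node labels."""
    node_binary = np.asarray(node_binary)
    if len(node_binary) != mesh.n_vertices:
        raise InvalidInputError("node label length must match vertex count")
    votes = node_binary[mesh.faces].sum(axis=1)
    return (votes >= 2).astype(np.float64)


def smooth_materials(mesh: SurfaceMesh, element_material: np.ndarray,
                     max_iter: int = 100,
                     adjacency: ElementAdjacency | None = None
                     ) -> tuple[np.ndarray, int, bool]:
    """Flip every element with >= 2 opposite-material edge neighbours until
    a sweep changes nothing or ``max_iter`` sweeps are used.

    Flips are applied sequentially in face-index order within each sweep:
    each flip removes at least one boundary edge, so the routine provably
    reaches a fixed point with zero rule violations (a synchronous update
    can blink forever on diagonal boundary runs).

    Returns ``(smoothed, iterations_used, converged)``.
    """
    mat = np.asarray(element_material, dtype=np.float64).copy()
    if len(mat) != mesh.n_faces:
        raise InvalidInputError("element material length must match face count")
    if adjacency is None:
        adjacency = build_adjacency(mesh)
    nbrs = adjacency.neighbors
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        flips = 0
        for i in range(mesh.n_faces):
            mi = mat[i]
            opposite = sum(1 for j in nbrs[i] if mat[j] != mi)
            if opposite >= 2:
                mat[i] = 1.0 - mi
                flips += 1
        if flips == 0:
            converged = True
            break
    if not converged:
        warnings.warn(f"material smoothing did not converge in {max_iter} sweeps")
    return mat, it, converged


def nodes_from_elements(mesh: SurfaceMesh, element_material: np.ndarray) -> np.ndarray:
    """Node label by majority of incident elements; ties resolve to enamel
    so the crown cap stays closed."""
    element_material = np.asarray(element_material, dtype=np.float64)
    incidence = vertex_face_incidence(mesh)
    out = np.zeros(mesh.n_vertices)
    for v, faces in enumerate(incidence):
        if not faces:
            continue
        enamel = element_material[faces].sum()
        out[v] = 1.0 if enamel * 2 >= len(faces) else 0.0
    return out


def extract_cej(mesh: SurfaceMesh, element_material: np.ndarray,
                adjacency: ElementAdjacency | None = None) -> CEJCurve:
    """Chain enamel/dentin boundary edges into closed vertex loops.

    Branch points (a boundary vertex with more than two boundary edges)
    abort the affected loop with a warning. A single-material mesh yields
    an empty curve with a warning.
    """
    element_material = np.asarray(element_material, dtype=np.float64)
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            edge_faces.setdefault(key, []).append(fi)
    boundary = [e for e, fl in edge_faces.items()
                if len(fl) == 2 and element_material[fl[0]] != element_material[fl[1]]]
    if not boundary:
        warnings.warn("mesh is single-material: no CEJ boundary found")
        return CEJCurve()
    # vertex -> adjacent boundary vertices
    link: dict[int, list[int]] = {}
    for u, v in boundary:
        link.setdefault(u, []).append(v)
        link.setdefault(v, []).append(u)
    unused = {tuple(sorted(e)) for e in boundary}
    loops: list[list[int]] = []
    while unused:
        start, second = min(unused)
        unused.discard((start, second))
        loop = [start]
        prev, cur = start, second
        ok = True
        while cur != start:
            loop.append(cur)
            if len(link[cur]) != 2:
                warnings.warn(f"branching CEJ boundary at vertex {cur}; loop aborted")
                ok = False
                break
            nxt = link[cur][0] if link[cur][0] != prev else link[cur][1]
            edge = (cur, nxt) if cur < nxt else (nxt, cur)
            if edge not in unused:  # open chain or edge re-use
                ok = False
                break
            unused.discard(edge)
            prev, cur = cur, nxt
        if ok and len(loop) >= 3:
            loops.append(loop)
    lengths = []
    for loop in loops:
        pts = mesh.vertices[np.asarray(loop)]
        seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        lengths.append(float(seg.sum()))
    order = np.argsort(lengths)[::-1]
    return CEJCurve(loops=[loops[i] for i in order],
                    lengths=[lengths[i] for i in order])
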