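"""Elastic (template-morphing) registration.

The baseline mesh, already scaled and rigidly aligned to the target, is
iteratively attracted toward nearest target vertices with a fixed step
fraction, with one synchronous Laplacian smoothing pass per iteration
whose weight decays geometrically so late iterations fit fine detail.
Connectivity never changes, so registered specimens share node indexing
with the baseline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .align import bbox_scale, icp, origin_align
from .cohort import RegisteredCohort, ShapeVector
from .errors import InvalidInputError, RegistrationError
from .mesh import SurfaceMesh, nearest_vertices

__all__ = [
    "RegistrationParams", "QualityReport", "laplacian_smooth",
    "elastic_register", "compute_mean_shape", "transfer_material",
    "two_pass_register",
]


@dataclass(frozen=True)
class RegistrationParams:
    alpha: float = 0.5          # fraction of the step toward the nearest target vertex
    lambda0: float = 0.5        # initial Laplacian smoothing weight
    decay: float = 0.9          # geometric decay of the smoothing weight
    tol: float = 1e-4           # mm mean-displacement stopping threshold
    max_iter: int = 200
    icp_max_iter: int = 100
    icp_tol: float = 1e-6
    material_delta: float | None = None  # mm; None = 0.5 x median enamel edge length


@dataclass
class QualityReport:
    mean_distance: float
    max_distance: float
    min_triangle_quality: float
    n_iterations: int
    converged: bool
    distance_trace: list = field(default_factory=list)


def _adjacency_operator(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Row-normalised vertex 1-ring averaging operator."""
    e = mesh.edges()
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.ones(len(rows))
    a = sparse.csr_matrix((data, (rows, cols)), shape=(mesh.n_vertices, mesh.n_vertices))
    deg = np.asarray(a.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    inv = sparse.diags(1.0 / deg)
    return inv @ a


def laplacian_smooth(mesh: SurfaceMesh, weight: float, passes: int = 1) -> SurfaceMesh:
    """Synchronous (Jacobi) Laplacian smoothing: each vertex moves by
    ``weight`` times the offset to its 1-ring centroid, ``passes`` times."""
    if not 0.0 <= weight <= 1.0:
        raise InvalidInputError("weight must be in [0, 1]")
    if weight == 0.0 or passes == 0:
        return mesh.copy()
    op = _adjacency_operator(mesh)
    v = mesh.vertices.copy()
    for _ in range(passes):
        v = (1.0 - weight) * v + weight * (op @ v)
    return mesh.with_vertices(v)


def triangle_quality(mesh: SurfaceMesh) -> np.ndarray:
    """Per-face quality 2 * inradius / circumradius (1 for equilateral)."""
    v = mesh.vertices
    f = mesh.faces
    a = np.linalg.norm(v[f[:, 1]] - v[f[:, 2]], axis=1)
    b = np.linalg.norm(v[f[:, 0]] - v[f[:, 2]], axis=1)
    c = np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        inr = np.where(s > 0, area / s, 0.0)
        circ = np.where(area > 0, a * b * c / (4.0 * area), np.inf)
        q = np.where(np.isfinite(circ) & (circ > 0), 2.0 * inr / circ, 0.0)
    return q


def elastic_register(baseline: SurfaceMesh, target: SurfaceMesh,
                     params: RegistrationParams = RegistrationParams()
                     ) -> tuple[SurfaceMesh, QualityReport]:
    """Morph the (pre-aligned, pre-scaled) baseline onto the target.

    Returns the morphed mesh on baseline connectivity plus a quality
    report. Divergence (mean distance increasing for 10 consecutive
    iterations) raises :class:`RegistrationError`; inverted faces only
    warn.
    """
    if baseline.n_vertices == 0 or target.n_vertices == 0:
        raise InvalidInputError("meshes must be non-empty")
    tree = cKDTree(target.vertices)
    op = _adjacency_operator(baseline)
    v = baseline.vertices.copy()
    initial_normals = baseline.face_normals()
    lam = params.lambda0
    trace = []
    n_increase = 0
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        prev = v
        _, idx = tree.query(v)
        v = v + params.alpha * (target.vertices[idx] - v)
        if lam > 0:
            v = (1.0 - lam) * v + lam * (op @ v)
        lam *= params.decay
        d, _ = tree.query(v)
        mean_d = float(np.mean(d))
        if trace and mean_d > trace[-1]:
            n_increase += 1
            if n_increase >= 10:
                raise RegistrationError(
                    "elastic registration diverging (10 consecutive increases)",
                    trace=trace)
        else:
            n_increase = 0
        trace.append(mean_d)
        mean_disp = float(np.mean(np.linalg.norm(v - prev, axis=1)))
        if mean_disp < params.tol:
            converged = True
            break
    result = baseline.with_vertices(v)
    flipped = np.where(np.einsum("ij,ij->i", result.face_normals(), initial_normals) < 0)[0]
    if flipped.size:
        warnings.warn(f"{flipped.size} face(s) inverted during registration: "
                      f"{flipped[:20].tolist()}")
    d, _ = tree.query(v)
    report = QualityReport(
        mean_distance=float(np.mean(d)),
        max_distance=float(np.max(d)),
        min_triangle_quality=float(triangle_quality(result).min()),
        n_iterations=it,
        converged=converged,
        distance_trace=trace,
    )
    return result, report


def compute_mean_shape(cohort: RegisteredCohort) -> ShapeVector:
    """Componentwise arithmetic mean of the cohort's shape vectors."""
    if cohort.n_specimens == 0:
        raise InvalidInputError("cohort is empty")
    return ShapeVector(cohort.matrix().mean(axis=0), has_material=cohort.has_material)


def transfer_material(registered: SurfaceMesh, enamel_mesh: SurfaceMesh,
                      delta: float | None = None) -> np.ndarray:
    """Per-node I: 1 iff the node lies within ``delta`` mm of the specimen's
    enamel mesh (nearest-vertex distance), else 0.

    ``delta=None`` uses 0.5 x the enamel mesh's median edge length;
    ``delta=inf`` reproduces a bare nearest-neighbour lookup (always 1).
    """
    if enamel_mesh.n_vertices == 0:
        warnings.warn("empty enamel mesh: labelling every node dentin")
        return np.zeros(registered.n_vertices)
    if delta is None:
        delta = 0.5 * enamel_mesh.median_edge_length()
    _, dist = nearest_vertices(registered.vertices, enamel_mesh.vertices)
    return (dist <= delta).astype(np.float64)


def _register_one(baseline: SurfaceMesh, target: SurfaceMesh,
                  params: RegistrationParams) -> tuple[SurfaceMesh, QualityReport]:
    """Full per-specimen chain: bbox scale -> origin align -> ICP -> elastic."""
    scaled, _ = bbox_scale(baseline, target)
    shift = origin_align(scaled, target)
    scaled = shift.apply_mesh(scaled)
    res = icp(scaled, target, max_iter=params.icp_max_iter, tol=params.icp_tol)
    aligned = res.transform.apply_mesh(scaled)
    return elastic_register(aligned, target, params)


def two_pass_register(training: list[tuple[SurfaceMesh, SurfaceMesh]],
                      initial_baseline: SurfaceMesh,
                      params: RegistrationParams = RegistrationParams(),
                      ids: list[str] | None = None,
                      groups: list[str] | None = None,
                      use_material: bool = True) -> RegisteredCohort:
    """Register every (whole mesh, enamel mesh) specimen twice: first from
    ``initial_baseline``, then from the pass-1 mean shape, after which
    enamel labels are transferred. Per-pass quality lands in
    ``cohort.metadata``.
    """
    if len(training) < 2:
        raise InvalidInputError("need at least 2 training specimens")
    ids = ids or [f"spec{i:03d}" for i in range(len(training))]
    groups = groups or ["all"] * len(training)

    def run_pass(baseline: SurfaceMesh):
        registered, reports = [], []
        for sid, (whole, _) in zip(ids, training):
            try:
                morphed, rep = _register_one(baseline, whole, params)
            except RegistrationError as exc:
                raise RegistrationError(f"registration failed for specimen {sid}: {exc}",
                                        trace=getattr(exc, "trace", None)) from exc
            registered.append(morphed)
            reports.append(rep)
        return registered, reports

    pass1, reports1 = run_pass(initial_baseline)
    mean_vertices = np.mean([m.vertices for m in pass1], axis=0)
    mean_mesh = SurfaceMesh(mean_vertices, initial_baseline.faces.copy())
    pass2, reports2 = run_pass(mean_mesh)

    vectors = []
    for morphed, (_, enamel) in zip(pass2, training):
        mat = transfer_material(morphed, enamel, params.material_delta) if use_material else None
        vectors.append(ShapeVector.from_mesh_arrays(morphed.vertices, mat))
    return RegisteredCohort(
        faces=initial_baseline.faces.copy(),
        vectors=vectors,
        ids=list(ids),
        groups=list(groups),
        metadata={
            "pass1_mean_distance": float(np.mean([r.mean_distance for r in reports1])),
            "pass2_mean_distance": float(np.mean([r.mean_distance for r in reports2])),
            "pass1_reports": reports1,
            "pass2_reports": reports2,
        },
    )
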