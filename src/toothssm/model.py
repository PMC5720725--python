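"""Correlation-method PCA over registered shape vectors.

Because coordinates (mm) and material labels (unitless) mix units, every
variable is standardised before decomposition and the per-variable scale
is re-applied when generating instances:

    x = mean + scale * (sum_j phi_j d_j)

Weights are handled either raw (score units) or in per-PC standard
deviations (sigma units, d_j = w_j * sqrt(lambda_j)).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import RegisteredCohort, ShapeVector
from .errors import InvalidInputError
from .mesh import SurfaceMesh, nearest_vertices

__all__ = [
    "ShapeModel", "PCWeights", "fit_model", "generate_instance", "project",
    "variance_report", "choose_c", "sigma_sweep", "reconstruction_error_test",
    "reconstruction_error_vectorspace",
]

_EIGENVALUE_FLOOR = 1e-12  # relative; below this a PC is considered trivial


@dataclass
class PCWeights:
    coefficients: np.ndarray
    sigma_units: bool = False

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.coefficients)):
            raise InvalidInputError("weights must be finite")

    def raw(self, eigenvalues: np.ndarray) -> np.ndarray:
        if not self.sigma_units:
            return self.coefficients
        k = len(self.coefficients)
        return self.coefficients * np.sqrt(eigenvalues[:k])

    def in_sigma_units(self, eigenvalues: np.ndarray) -> np.ndarray:
        if self.sigma_units:
            return self.coefficients
        k = len(self.coefficients)
        sd = np.sqrt(eigenvalues[:k])
        sd[sd == 0] = 1.0
        return self.coefficients / sd


@dataclass
class ShapeModel:
    mean: np.ndarray                 # full-length mean vector
    scale: np.ndarray                # per-variable sd (ddof=1), full length
    constant_mask: np.ndarray        # True where the variable is constant
    eigenvectors: np.ndarray         # (n_active, c) orthonormal, standardised space
    eigenvalues: np.ndarray          # descending PC score variances
    n_samples: int
    has_material: bool
    material_mask: np.ndarray | None = None  # full-length flag of material variables
    metadata: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_variables(self) -> int:
        return len(self.mean)

    @property
    def active_indices(self) -> np.ndarray:
        return np.where(~self.constant_mask)[0]

    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def fit_model(cohort: RegisteredCohort, use_material: bool = True,
              epsilon: float = 1e-8) -> ShapeModel:
    """Fit the PCA model by SVD of the standardised N x V data matrix.

    Variables with standard deviation below ``epsilon`` are marked constant
    and excluded from the basis (they are emitted at their constant value
    on generation). The V x V correlation matrix is never formed.
    """
    if cohort.n_specimens < 2:
        raise InvalidInputError("need at least 2 specimens to fit a model")
    x = cohort.matrix()
    material_mask = None
    has_material = cohort.has_material
    if cohort.has_material and not use_material:
        keep = np.ones(x.shape[1], dtype=bool)
        keep.reshape(-1, 4)[:, 3] = False
        x = x[:, keep]
        has_material = False
    if has_material:
        material_mask = np.zeros(x.shape[1], dtype=bool)
        material_mask.reshape(-1, 4)[:, 3] = True

    n = x.shape[0]
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    constant = scale < epsilon
    active = ~constant
    z = (x[:, active] - mean[active]) / scale[active]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigenvalues = s * s / (n - 1)
    if eigenvalues.size:
        keep = eigenvalues > _EIGENVALUE_FLOOR * max(eigenvalues[0], 1.0)
    else:
        keep = np.zeros(0, dtype=bool)
    eigenvalues = eigenvalues[keep]
    phi = vt[keep].T  # (n_active, c)
    # deterministic sign: largest-magnitude loading of each PC made positive
    for j in range(phi.shape[1]):
        k = np.argmax(np.abs(phi[:, j]))
        if phi[k, j] < 0:
            phi[:, j] = -phi[:, j]
    return ShapeModel(
        mean=mean, scale=scale, constant_mask=constant,
        eigenvectors=phi, eigenvalues=eigenvalues, n_samples=n,
        has_material=has_material, material_mask=material_mask,
    )


def generate_instance(model: ShapeModel, weights: PCWeights,
                      c: int | None = None, clamp_material: bool = True) -> ShapeVector:
    """Instance x = mean + scale * (Phi[:, :c] @ d); material components are
    clamped into [0, 1] (probabilistic labels)."""
    if c is None:
        c = model.n_components
    if c > model.n_components:
        raise InvalidInputError(
            f"c = {c} exceeds the {model.n_components} available PCs")
    d = weights.raw(model.eigenvalues)
    if len(d) < c:
        d = np.concatenate([d, np.zeros(c - len(d))])
    d = d[:c]
    x = model.mean.copy()
    active = model.active_indices
    x[active] = x[active] + model.scale[active] * (model.eigenvectors[:, :c] @ d)
    if clamp_material and model.material_mask is not None:
        x[model.material_mask] = np.clip(x[model.material_mask], 0.0, 1.0)
    return ShapeVector(x, has_material=model.has_material)


def project(model: ShapeModel, shape: ShapeVector | np.ndarray) -> PCWeights:
    """Raw-unit weights d = Phi^T ((x - mean) / scale) over active variables."""
    values = shape.values if isinstance(shape, ShapeVector) else np.asarray(shape, float).ravel()
    if len(values) != model.n_variables:
        raise InvalidInputError(
            f"shape length {len(values)} does not match model ({model.n_variables})")
    active = model.active_indices
    z = (values[active] - model.mean[active]) / model.scale[active]
    return PCWeights(model.eigenvectors.T @ z, sigma_units=False)


def variance_report(model: ShapeModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-PC variance fraction and cumulative fraction."""
    frac = model.variance_fractions()
    return frac, np.cumsum(frac)


def choose_c(model: ShapeModel, cumulative_target: float) -> int:
    """Smallest number of PCs whose cumulative variance fraction reaches the
    target."""
    if not 0.0 < cumulative_target <= 1.0:
        raise InvalidInputError("cumulative target must be in (0, 1]")
    _, cum = variance_report(model)
    if len(cum) == 0:
        return 0
    hit = np.where(cum >= cumulative_target - 1e-12)[0]
    return int(hit[0]) + 1 if hit.size else len(cum)


def sigma_sweep(model: ShapeModel, pc: int,
                levels=(-3, -2, -1, 0, 1, 2, 3)) -> list[ShapeVector]:
    """One instance per sigma level of a single PC (1-based index), all other
    weights zero."""
    if not 1 <= pc <= model.n_components:
        raise InvalidInputError(f"pc {pc} out of range 1..{model.n_components}")
    out = []
    for level in levels:
        w = np.zeros(pc)
        w[pc - 1] = level
        out.append(generate_instance(model, PCWeights(w, sigma_units=True), c=pc))
    return out


def reconstruction_error_test(model: ShapeModel, cohort: RegisteredCohort,
                              faces: np.ndarray | None = None,
                              k_range=None) -> np.ndarray:
    """Mean surface error (mm) of each training specimen reconstructed with
    its first k projected weights, for each k.

    The error is the mean over reconstructed nodes of the Euclidean
    distance to the nearest node of the target specimen. Returns an array
    of shape (len(k_range), N) for boxplotting.
    """
    x = cohort.matrix()
    if x.shape[1] != model.n_variables:
        raise InvalidInputError("cohort does not match the fitted model")
    if k_range is None:
        k_range = range(model.n_components + 1)
    k_range = list(k_range)
    errors = np.zeros((len(k_range), cohort.n_specimens))
    for i, vec in enumerate(cohort.vectors):
        w = project(model, vec).coefficients
        target = vec.coords()
        for ki, k in enumerate(k_range):
            recon = generate_instance(model, PCWeights(w[:k]), c=k)
            _, d = nearest_vertices(recon.coords(), target)
            errors[ki, i] = float(np.mean(d))
    return errors


def reconstruction_error_vectorspace(model: ShapeModel, cohort: RegisteredCohort,
                                     k_range=None) -> np.ndarray:
    """Residual 2-norm in standardised variable space per specimen per k;
    exactly monotone non-increasing in k."""
    if k_range is None:
        k_range = range(model.n_components + 1)
    k_range = list(k_range)
    active = model.active_indices
    x = cohort.matrix()
    z = (x[:, active] - model.mean[active]) / model.scale[active]
    scores = z @ model.eigenvectors  # (N, c)
    errors = np.zeros((len(k_range), cohort.n_specimens))
    for ki, k in enumerate(k_range):
        recon = scores[:, :k] @ model.eigenvectors[:, :k].T
        errors[ki] = np.linalg.norm(z - recon, axis=1)
    return errors


def mean_mesh(model: ShapeModel, faces: np.ndarray) -> SurfaceMesh:
    """The mean shape as a mesh (material carried if modelled)."""
    vec = ShapeVector(model.mean, has_material=model.has_material)
    return SurfaceMesh(vec.coords(), faces, vec.materials())
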