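"""Parametric generator of canine-like closed surface meshes with
enamel/dentin labels, and of seeded study populations with known modes
of variation.

Geometry is a surface of revolution with azimuth-dependent elliptical
radius. The crown is a convex elliptical cap whose apex is the incisal
edge at max z; the root tapers to a single apex at min z, optionally
sheared mesially (+x) for curvature. The enamel/dentin boundary height
varies sinusoidally with azimuth: peaks on the mesial/distal (+/-x)
sides, troughs on the labial/lingual (+/-y) sides. Every inter-landmark
measurement therefore has a closed-form target
(:func:`expected_measurements`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import RegisteredCohort, ShapeVector
from .errors import InvalidInputError
from .mesh import SurfaceMesh, signed_volume, submesh

__all__ = [
    "ToothParams", "GroupSpec", "PopulationSpec", "Specimen",
    "generate_tooth", "generate_population", "enamel_submesh",
    "expected_measurements", "cohort_from_specimens",
]


@dataclass(frozen=True)
class ToothParams:
    """Generative parameters of one tooth (mm unless noted)."""

    crown_length: float = 11.0
    root_length: float = 16.0
    md_diameter_crown: float = 7.0
    ll_diameter_crown: float = 8.0
    md_diameter_cervix: float = 5.5
    ll_diameter_cervix: float = 7.5
    root_curvature: float = 1.0       # mesio-distal apex offset
    apex_taper: float = 1.5           # dimensionless exponent > 0
    cej_amplitude: float = 1.5        # CEJ peak-to-trough height
    mesh_resolution: tuple = (48, 56)  # (azimuthal, axial) sample counts

    def validate(self) -> None:
        lengths = (self.crown_length, self.root_length, self.md_diameter_crown,
                   self.ll_diameter_crown, self.md_diameter_cervix,
                   self.ll_diameter_cervix)
        if any(v <= 0 for v in lengths):
            raise InvalidInputError("all tooth lengths/diameters must be > 0")
        if self.apex_taper <= 0:
            raise InvalidInputError("apex_taper must be > 0")
        if not 0 <= self.cej_amplitude < self.crown_length:
            raise InvalidInputError("cej_amplitude must be in [0, crown_length)")
        if self.md_diameter_cervix >= self.md_diameter_crown or \
                self.ll_diameter_cervix >= self.ll_diameter_crown:
            raise InvalidInputError("cervix diameters must be below crown diameters")
        n_theta, n_axial = self.mesh_resolution
        if n_theta < 8:
            raise InvalidInputError(
                f"{n_theta} azimuthal samples cannot resolve the CEJ (need >= 8)")
        if n_axial < 8:
            raise InvalidInputError("need at least 8 axial samples")

    def scaled(self, s: float) -> "ToothParams":
        """All length parameters multiplied by ``s`` (taper unchanged)."""
        return replace(
            self,
            crown_length=self.crown_length * s,
            root_length=self.root_length * s,
            md_diameter_crown=self.md_diameter_crown * s,
            ll_diameter_crown=self.ll_diameter_crown * s,
            md_diameter_cervix=self.md_diameter_cervix * s,
            ll_diameter_cervix=self.ll_diameter_cervix * s,
            root_curvature=self.root_curvature * s,
            cej_amplitude=self.cej_amplitude * s,
        )


def _cej_height(theta: np.ndarray, amplitude: float) -> np.ndarray:
    # peaks (+z) at theta = 0, pi (mesial/distal); troughs at +/- pi/2
    return 0.5 * amplitude * np.cos(2.0 * theta)


def generate_tooth(params: ToothParams) -> tuple[SurfaceMesh, np.ndarray]:
    """Build one closed tooth mesh plus per-vertex material I in {0, 1}."""
    params.validate()
    n_theta, n_axial = params.mesh_resolution
    lc, lr = params.crown_length, params.root_length
    a_max = params.md_diameter_crown / 2.0
    b_max = params.ll_diameter_crown / 2.0
    a_cerv = params.md_diameter_cervix / 2.0
    b_cerv = params.ll_diameter_cervix / 2.0
    u0a = math.sqrt(1.0 - (a_cerv / a_max) ** 2)
    u0b = math.sqrt(1.0 - (b_cerv / b_max) ** 2)

    n_root = max(4, int(round(n_axial * lr / (lr + lc))))
    n_crown = max(4, n_axial - n_root)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    rings = []  # (z, a, b, xshift)
    for t in np.linspace(1.0, 0.0, n_root + 1)[1:]:
        g = (1.0 - t) ** params.apex_taper
        rings.append((-t * lr, a_cerv * g, b_cerv * g, params.root_curvature * t * t))
    for z in np.linspace(0.0, lc, n_crown + 1)[1:-1]:
        ua = -u0a + (1.0 + u0a) * z / lc
        ub = -u0b + (1.0 + u0b) * z / lc
        rings.append((z, a_max * math.sqrt(max(0.0, 1.0 - ua * ua)),
                      b_max * math.sqrt(max(0.0, 1.0 - ub * ub)), 0.0))

    verts = [np.array([params.root_curvature, 0.0, -lr])]  # root apex
    vert_theta = [0.0]
    for z, a, b, xs in rings:
        ring = np.column_stack([a * cos_t + xs, b * sin_t, np.full(n_theta, z)])
        verts.append(ring)
        vert_theta.append(theta)
    verts.append(np.array([0.0, 0.0, lc]))  # incisal tip
    vert_theta.append(0.0)
    vertices = np.vstack([np.atleast_2d(v) for v in verts])
    theta_of = np.concatenate([np.atleast_1d(t) for t in vert_theta])

    n_rings = len(rings)
    tip = 1 + n_rings * n_theta
    faces = []
    for k in range(n_theta):  # apex fan (ring 0 starts at vertex 1)
        faces.append((0, 1 + (k + 1) % n_theta, 1 + k))
    for r in range(n_rings - 1):
        base = 1 + r * n_theta
        nxt = base + n_theta
        for k in range(n_theta):
            k1 = (k + 1) % n_theta
            faces.append((base + k, base + k1, nxt + k1))
            faces.append((base + k, nxt + k1, nxt + k))
    base = 1 + (n_rings - 1) * n_theta
    for k in range(n_theta):  # tip fan
        faces.append((base + k, base + (k + 1) % n_theta, tip))
    mesh = SurfaceMesh(vertices, np.asarray(faces, dtype=np.int64))
    if signed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()

    material = (vertices[:, 2] >= _cej_height(theta_of, params.cej_amplitude)).astype(np.float64)
    material[0] = 0.0          # root apex is dentin
    material[tip] = 1.0        # incisal tip is enamel
    mesh.vertex_material = material
    return mesh, material


def enamel_submesh(mesh: SurfaceMesh, material: np.ndarray) -> SurfaceMesh:
    """Sub-mesh of the enamel-labelled region (faces fully enamel)."""
    return submesh(mesh, np.asarray(material) >= 0.5)


def expected_measurements(params: ToothParams) -> dict[str, float]:
    """Closed-form targets for the inter-landmark measurements of a
    noise-free generated tooth (continuum limit of the mesh)."""
    amp = params.cej_amplitude
    lr, lc = params.root_length, params.crown_length
    a_max = params.md_diameter_crown / 2.0
    b_cerv = params.ll_diameter_cervix / 2.0
    a_cerv = params.md_diameter_cervix / 2.0
    # labial/lingual CEJ troughs sit on the root profile at z = -amp/2
    t_tr = (amp / 2.0) / lr
    b_tr = b_cerv * (1.0 - t_tr) ** params.apex_taper
    # mesial/distal CEJ peaks sit on the crown profile at z = +amp/2
    u0a = math.sqrt(1.0 - (a_cerv / a_max) ** 2)
    ua = -u0a + (1.0 + u0a) * (amp / 2.0) / lc
    a_pk = a_max * math.sqrt(max(0.0, 1.0 - ua * ua))
    ra = np.array([params.root_curvature, 0.0, -lr])
    cejtla = np.array([0.0, b_tr, -amp / 2.0])
    cmie = np.array([0.0, 0.0, lc])
    return {
        "LDC": params.ll_diameter_crown,
        "MDC": params.md_diameter_crown,
        "LDCc": 2.0 * b_tr,
        "MDCc": 2.0 * a_pk,
        "LORla": float(np.linalg.norm(ra - cejtla)),
        "LOCla": float(np.linalg.norm(cmie - cejtla)),
    }


# ---------------------------------------------------------------- populations

@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int
    params: ToothParams = field(default_factory=ToothParams)
    scale_shift: float = 1.0  # multiplies the group's mean overall scale

    def validate(self) -> None:
        if self.n < 1:
            raise InvalidInputError("group n must be >= 1")
        self.params.validate()


@dataclass(frozen=True)
class PopulationSpec:
    """Population-level modes of variation plus per-parameter jitter.

    Modes: ``scale_cv`` (overall scale), ``ratio_cv`` (crown:root length
    ratio), ``cervix_cv`` (cervical root widths), ``curvature_sd``
    (additive mm on the apex offset). ``param_cv`` adds independent
    log-normal jitter to each positive parameter. Surface noise is
    applied along vertex normals so closedness is preserved.
    """

    groups: tuple = (GroupSpec("A", 6),)
    param_cv: float = 0.0
    scale_cv: float = 0.0
    ratio_cv: float = 0.0
    cervix_cv: float = 0.0
    curvature_sd: float = 0.0
    noise_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise InvalidInputError("population needs at least one group")
        for g in self.groups:
            g.validate()
        if self.noise_amplitude < 0:
            raise InvalidInputError("noise amplitude must be >= 0")
        for cv in (self.param_cv, self.scale_cv, self.ratio_cv, self.cervix_cv):
            if cv < 0:
                raise InvalidInputError("coefficients of variation must be >= 0")


@dataclass
class Specimen:
    id: str
    group: str
    mesh: SurfaceMesh
    material: np.ndarray
    params: ToothParams
    modes: dict


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 log-normal draw with coefficient of variation ``cv``."""
    z = rng.standard_normal()
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return math.exp(sigma * z - 0.5 * sigma * sigma)


def generate_population(spec: PopulationSpec) -> list[Specimen]:
    """Deterministic (seeded) population draw; true generative parameters
    and mode factors are returned with every specimen for recovery tests."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    specimens: list[Specimen] = []
    idx = 0
    for group in spec.groups:
        base = group.params
        for _ in range(group.n):
            s_scale = _lognormal(rng, spec.scale_cv) * group.scale_shift
            s_ratio = _lognormal(rng, spec.ratio_cv)
            s_cervix = _lognormal(rng, spec.cervix_cv)
            d_curv = rng.standard_normal() * spec.curvature_sd
            jit = [_lognormal(rng, spec.param_cv) for _ in range(8)]
            md_crown = base.md_diameter_crown * s_scale * jit[2]
            ll_crown = base.ll_diameter_crown * s_scale * jit[3]
            params = replace(
                base,
                crown_length=base.crown_length * s_scale * s_ratio * jit[0],
                root_length=base.root_length * s_scale / s_ratio * jit[1],
                md_diameter_crown=md_crown,
                ll_diameter_crown=ll_crown,
                md_diameter_cervix=min(base.md_diameter_cervix * s_scale * s_cervix * jit[4],
                                       0.98 * md_crown),
                ll_diameter_cervix=min(base.ll_diameter_cervix * s_scale * s_cervix * jit[5],
                                       0.98 * ll_crown),
                cej_amplitude=base.cej_amplitude * s_scale * jit[6],
                apex_taper=base.apex_taper * jit[7],
                root_curvature=base.root_curvature * s_scale + d_curv,
            )
            mesh, material = generate_tooth(params)
            if spec.noise_amplitude > 0:
                normals = mesh.vertex_normals()
                offsets = rng.standard_normal(mesh.n_vertices) * spec.noise_amplitude
                mesh = mesh.with_vertices(mesh.vertices + offsets[:, None] * normals)
            else:
                rng.standard_normal(mesh.n_vertices)  # keep stream layout stable
            specimens.append(Specimen(
                id=f"{group.name}{idx:03d}",
                group=group.name,
                mesh=mesh,
                material=material,
                params=params,
                modes={"scale": s_scale, "ratio": s_ratio,
                       "cervix": s_cervix, "curvature": params.root_curvature},
            ))
            idx += 1
    return specimens


def cohort_from_specimens(specimens: list[Specimen],
                          use_material: bool = True) -> RegisteredCohort:
    """Build a registered cohort directly from generator output.

    All specimens drawn at the same ``mesh_resolution`` share connectivity
    by construction, so the generator's own node indexing already provides
    point-to-point correspondence.
    """
    if not specimens:
        raise InvalidInputError("no specimens")
    faces = specimens[0].mesh.faces
    vectors = []
    for s in specimens:
        if s.mesh.n_vertices != specimens[0].mesh.n_vertices:
            raise InvalidInputError(
                "specimens have differing node counts; register them instead")
        mat = s.material if use_material else None
        vectors.append(ShapeVector.from_mesh_arrays(s.mesh.vertices, mat))
    return RegisteredCohort(
        faces=faces,
        vectors=vectors,
        ids=[s.id for s in specimens],
        groups=[s.group for s in specimens],
        metadata={"source": "generator-correspondence"},
    )
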