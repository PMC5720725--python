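"""Configuration-driven orchestration of the full pipeline:

synth -> align -> register -> fit -> sweep -> cej -> landmarks -> measure -> stats

Every stage writes its artifacts under the configured output directory
and appends a log line; stages re-load prerequisites from disk when run
individually, so subcommands can resume a previous run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as mesh_io
from .align import bbox_scale, icp, origin_align
from .cej import extract_cej, elements_from_nodes
from .cohort import RegisteredCohort, ShapeVector
from .elastic import RegistrationParams, two_pass_register, transfer_material
from .errors import InvalidInputError, ToothSSMError
from .landmarks import (MEASUREMENT_NAMES, detect_landmarks, measure,
                        measure_instance, measure_sweep)
from .mesh import SurfaceMesh
from .model import (ShapeModel, choose_c, fit_model, mean_mesh, project,
                    variance_report)
from .stats import bland_altman, compare_groups, pc_measurement_regressions
from .synth import (GroupSpec, PopulationSpec, ToothParams, enamel_submesh,
                    generate_population)

log = logging.getLogger("toothssm.pipeline")

STAGES = ("synth", "align", "register", "fit", "sweep", "cej",
          "landmarks", "measure", "stats")


@dataclass
class PipelineConfig:
    outdir: str = "toothssm_run"
    seed: int = 0
    manifest: str | None = None          # existing specimen manifest, or None to synthesise
    synth: dict = field(default_factory=dict)
    alignment: dict = field(default_factory=dict)
    registration: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    sweep_levels: tuple = (-3, -2, -1, 0, 1, 2, 3)
    regression_alpha: float = 0.01
    anova_alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < float(self.pca.get("cumulative_target", 0.95)) <= 1.0:
            raise InvalidInputError("cumulative variance target must be in (0, 1]")
        for key in ("tol", "max_iter"):
            if key in self.registration and self.registration[key] <= 0:
                raise InvalidInputError(f"registration {key} must be > 0")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        if "sweep_levels" in raw:
            raw["sweep_levels"] = tuple(raw["sweep_levels"])
        return cls(**raw)

    def registration_params(self) -> RegistrationParams:
        return RegistrationParams(**self.registration)


@dataclass
class PipelineReport:
    completed: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _population_spec(cfg: PipelineConfig) -> PopulationSpec:
    s = cfg.synth
    base_kwargs = dict(s.get("base_params", {}))
    if "resolution" in s:
        base_kwargs["mesh_resolution"] = tuple(s["resolution"])
    base = ToothParams(**base_kwargs)
    groups = tuple(
        GroupSpec(name=g["name"], n=int(g["n"]), params=base,
                  scale_shift=float(g.get("scale_shift", 1.0)))
        for g in s.get("groups", [{"name": "A", "n": 6}])
    )
    return PopulationSpec(
        groups=groups,
        param_cv=float(s.get("param_cv", 0.05)),
        scale_cv=float(s.get("scale_cv", 0.0)),
        ratio_cv=float(s.get("ratio_cv", 0.0)),
        cervix_cv=float(s.get("cervix_cv", 0.0)),
        curvature_sd=float(s.get("curvature_sd", 0.0)),
        noise_amplitude=float(s.get("noise_amplitude", 0.0)),
        seed=cfg.seed,
    )


# ---------------------------------------------------------------- stages

def stage_synth(cfg: PipelineConfig, state: dict) -> None:
    outdir = os.path.join(cfg.outdir, "meshes")
    os.makedirs(outdir, exist_ok=True)
    specimens = generate_population(_population_spec(cfg))
    rows = []
    for s in specimens:
        whole = os.path.join(outdir, f"{s.id}_whole.ply")
        enamel = os.path.join(outdir, f"{s.id}_enamel.ply")
        mesh_io.save_mesh(s.mesh, whole)
        mesh_io.save_mesh(enamel_submesh(s.mesh, s.material), enamel)
        row = {"id": s.id, "group": s.group, "whole_mesh": whole, "enamel_mesh": enamel}
        row.update({f"true_{k}": v for k, v in dataclasses.asdict(s.params).items()
                    if isinstance(v, (int, float))})
        row.update({f"mode_{k}": v for k, v in s.modes.items()})
        rows.append(row)
    manifest = os.path.join(cfg.outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    state["manifest"] = manifest
    log.info("synth: %d specimens -> %s [%s]", len(rows), manifest, _hash_file(manifest))


def _load_manifest(cfg: PipelineConfig, state: dict) -> pd.DataFrame:
    manifest = state.get("manifest") or cfg.manifest or os.path.join(cfg.outdir, "manifest.csv")
    if not os.path.exists(manifest):
        raise ToothSSMError(f"stage needs manifest {manifest}; run 'synth' or provide one")
    state["manifest"] = manifest
    return pd.read_csv(manifest)


def stage_align(cfg: PipelineConfig, state: dict) -> None:
    df = _load_manifest(cfg, state)
    tdir = os.path.join(cfg.outdir, "transforms")
    os.makedirs(tdir, exist_ok=True)
    baseline_path = cfg.alignment.get("baseline") or df.iloc[0]["whole_mesh"]
    baseline = mesh_io.load_mesh(baseline_path)
    params = cfg.registration_params()
    for _, row in df.iterrows():
        target = mesh_io.load_mesh(row["whole_mesh"])
        scaled, factors = bbox_scale(baseline, target)
        shift = origin_align(scaled, target)
        res = icp(shift.apply_mesh(scaled), target,
                  max_iter=params.icp_max_iter, tol=params.icp_tol)
        total = res.transform.compose(shift)
        sidecar = {
            "id": row["id"],
            "scale_factors": [factors.sx, factors.sy, factors.sz],
            "matrix": total.to_matrix().tolist(),
            "icp_rms": res.rms,
            "icp_iterations": res.n_iterations,
        }
        path = os.path.join(tdir, f"{row['id']}.json")
        with open(path, "w") as fh:
            json.dump(sidecar, fh, indent=1)
    state["baseline_path"] = baseline_path
    log.info("align: %d transforms -> %s", len(df), tdir)


def stage_register(cfg: PipelineConfig, state: dict) -> None:
    df = _load_manifest(cfg, state)
    baseline_path = state.get("baseline_path") or cfg.alignment.get("baseline") \
        or df.iloc[0]["whole_mesh"]
    baseline = mesh_io.load_mesh(baseline_path)
    training = [(mesh_io.load_mesh(r["whole_mesh"]), mesh_io.load_mesh(r["enamel_mesh"]))
                for _, r in df.iterrows()]
    cohort = two_pass_register(
        training, baseline, cfg.registration_params(),
        ids=[str(i) for i in df["id"]], groups=[str(g) for g in df["group"]])
    rdir = os.path.join(cfg.outdir, "registered")
    os.makedirs(rdir, exist_ok=True)
    np.savetxt(os.path.join(rdir, "faces.txt"), cohort.faces, fmt="%d")
    rows = []
    for sid, group, vec in zip(cohort.ids, cohort.groups, cohort.vectors):
        path = os.path.join(rdir, f"{sid}_registered.ply")
        mesh_io.save_mesh(SurfaceMesh(vec.coords(), cohort.faces, vec.materials()), path)
        rows.append({"id": sid, "group": group, "registered_mesh": path})
    pd.DataFrame(rows).to_csv(os.path.join(rdir, "cohort.csv"), index=False)
    mean_vec = np.mean([v.coords() for v in cohort.vectors], axis=0)
    mesh_io.save_mesh(SurfaceMesh(mean_vec, cohort.faces), os.path.join(rdir, "mean.ply"))
    with open(os.path.join(rdir, "quality.json"), "w") as fh:
        json.dump({"pass1_mean_distance": cohort.metadata["pass1_mean_distance"],
                   "pass2_mean_distance": cohort.metadata["pass2_mean_distance"]}, fh, indent=1)
    state["cohort"] = cohort
    log.info("register: pass1 %.4f mm -> pass2 %.4f mm",
             cohort.metadata["pass1_mean_distance"], cohort.metadata["pass2_mean_distance"])


def _load_cohort(cfg: PipelineConfig, state: dict) -> RegisteredCohort:
    if "cohort" in state:
        return state["cohort"]
    rdir = os.path.join(cfg.outdir, "registered")
    faces_path = os.path.join(rdir, "faces.txt")
    cohort_csv = os.path.join(rdir, "cohort.csv")
    if not (os.path.exists(faces_path) and os.path.exists(cohort_csv)):
        raise ToothSSMError("stage needs a registered cohort; run 'register' first")
    faces = np.loadtxt(faces_path, dtype=np.int64).reshape(-1, 3)
    df = pd.read_csv(cohort_csv)
    vectors, ids, groups = [], [], []
    for _, row in df.iterrows():
        mesh = mesh_io.load_mesh(row["registered_mesh"])
        vectors.append(ShapeVector.from_mesh_arrays(mesh.vertices, mesh.vertex_material))
        ids.append(str(row["id"]))
        groups.append(str(row["group"]))
    cohort = RegisteredCohort(faces=faces, vectors=vectors, ids=ids, groups=groups)
    state["cohort"] = cohort
    return cohort


def stage_fit(cfg: PipelineConfig, state: dict) -> None:
    cohort = _load_cohort(cfg, state)
    model = fit_model(cohort,
                      use_material=bool(cfg.pca.get("use_material", True)),
                      epsilon=float(cfg.pca.get("epsilon", 1e-8)))
    mdir = os.path.join(cfg.outdir, "model")
    os.makedirs(mdir, exist_ok=True)
    np.savez(os.path.join(mdir, "model.npz"),
             mean=model.mean, scale=model.scale,
             constant_mask=model.constant_mask,
             eigenvectors=model.eigenvectors, eigenvalues=model.eigenvalues)
    frac, cum = variance_report(model)
    pd.DataFrame({"pc": np.arange(1, len(frac) + 1),
                  "variance_fraction": frac, "cumulative": cum}) \
        .to_csv(os.path.join(mdir, "variance.csv"), index=False)
    target = float(cfg.pca.get("cumulative_target", 0.95))
    c = choose_c(model, target)
    with open(os.path.join(mdir, "meta.json"), "w") as fh:
        json.dump({"n_samples": model.n_samples, "n_components": model.n_components,
                   "cumulative_target": target, "chosen_c": c,
                   "manifest_hash": _hash_file(state["manifest"]) if state.get("manifest") else None},
                  fh, indent=1)
    state["model"] = model
    state["chosen_c"] = c
    log.info("fit: %d PCs, c = %d at target %.2f", model.n_components, c, target)


def _load_model(cfg: PipelineConfig, state: dict) -> ShapeModel:
    if "model" in state:
        return state["model"]
    stage_fit(cfg, state)
    return state["model"]


def stage_sweep(cfg: PipelineConfig, state: dict) -> None:
    model = _load_model(cfg, state)
    cohort = _load_cohort(cfg, state)
    c = state.get("chosen_c") or choose_c(model, float(cfg.pca.get("cumulative_target", 0.95)))
    tables = [measure_sweep(model, cohort.faces, pc, levels=cfg.sweep_levels)
              for pc in range(1, c + 1)]
    rows = [row for table in tables for row in table]
    path = os.path.join(cfg.outdir, "sweeps.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    state["sweep_tables"] = tables
    log.info("sweep: PCs 1..%d x %d levels -> %s [%s]", c, len(cfg.sweep_levels),
             path, _hash_file(path))


def _specimen_materials(cohort: RegisteredCohort, index: int) -> np.ndarray:
    vec = cohort.vectors[index]
    if vec.has_material:
        return vec.materials()
    raise ToothSSMError("cohort carries no material labels")


def stage_cej(cfg: PipelineConfig, state: dict) -> None:
    cohort = _load_cohort(cfg, state)
    out = {}
    for i, sid in enumerate(cohort.ids):
        mesh = SurfaceMesh(cohort.vectors[i].coords(), cohort.faces)
        elem = elements_from_nodes(mesh, _specimen_materials(cohort, i) >= 0.5)
        curve = extract_cej(mesh, elem)
        out[sid] = {"n_loops": curve.n_loops, "lengths": curve.lengths,
                    "continuous": curve.is_continuous(),
                    "loops": [list(map(int, l)) for l in curve.loops]}
    path = os.path.join(cfg.outdir, "cej.json")
    with open(path, "w") as fh:
        json.dump(out, fh)
    log.info("cej: %d specimens -> %s", len(out), path)


def stage_landmarks(cfg: PipelineConfig, state: dict) -> None:
    cohort = _load_cohort(cfg, state)
    rows = []
    records = {}
    from .cej import binarize, smooth_materials, nodes_from_elements
    from .mesh import build_adjacency
    for i, sid in enumerate(cohort.ids):
        mesh = SurfaceMesh(cohort.vectors[i].coords(), cohort.faces)
        ih = binarize(np.clip(_specimen_materials(cohort, i), 0, 1))
        adjacency = build_adjacency(mesh)
        elem = elements_from_nodes(mesh, ih)
        elem, _, _ = smooth_materials(mesh, elem, adjacency=adjacency)
        nodes = nodes_from_elements(mesh, elem)
        curve = extract_cej(mesh, elem)
        lms = detect_landmarks(mesh, nodes, curve)
        records[sid] = (lms, mesh)
        for name, pt in lms.points.items():
            rows.append({"id": sid, "landmark": name, "x": pt[0], "y": pt[1],
                         "z": pt[2], "vertex_index": lms.indices[name]})
    path = os.path.join(cfg.outdir, "landmarks.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    state["landmark_records"] = records
    log.info("landmarks: %d specimens -> %s [%s]", len(records), path, _hash_file(path))


def stage_measure(cfg: PipelineConfig, state: dict) -> None:
    cohort = _load_cohort(cfg, state)
    if "landmark_records" not in state:
        stage_landmarks(cfg, state)
    rows = []
    for sid, group in zip(cohort.ids, cohort.groups):
        lms, mesh = state["landmark_records"][sid]
        rec = measure(lms, mesh)
        row = {"id": sid, "group": group}
        row.update(rec.as_dict())
        rows.append(row)
    path = os.path.join(cfg.outdir, "measurements.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    state["measurements"] = pd.DataFrame(rows)
    log.info("measure: %d specimens -> %s [%s]", len(rows), path, _hash_file(path))


def stage_stats(cfg: PipelineConfig, state: dict) -> None:
    cohort = _load_cohort(cfg, state)
    model = _load_model(cfg, state)
    sdir = os.path.join(cfg.outdir, "stats")
    os.makedirs(sdir, exist_ok=True)
    # Table-3 analogue: regression of sweep measurements on sigma level
    if "sweep_tables" not in state:
        stage_sweep(cfg, state)
    reg = pc_measurement_regressions(state["sweep_tables"], alpha=cfg.regression_alpha)
    pd.DataFrame(reg).to_csv(os.path.join(sdir, "pc_regressions.csv"), index=False)
    # group comparison per PC
    scores = np.vstack([project(model, v).coefficients for v in cohort.vectors])
    anova_out = {}
    c = state.get("chosen_c") or model.n_components
    for pc in range(1, min(c, model.n_components) + 1):
        res = compare_groups(scores[:, pc - 1], cohort.groups, alpha=cfg.anova_alpha)
        anova_out[f"PC{pc}"] = {
            "f_statistic": res.f_statistic, "p_value": res.p_value,
            "group_means": res.group_means, "posthoc": res.posthoc,
            "boxplots": res.boxplots,
        }
    with open(os.path.join(sdir, "anova.json"), "w") as fh:
        json.dump(anova_out, fh, indent=1)
    # Bland-Altman: registered-mesh measurements vs target-mesh measurements
    if "measurements" not in state:
        stage_measure(cfg, state)
    df = _load_manifest(cfg, state)
    reg_meas, tgt_meas = [], []
    for _, row in df.iterrows():
        target = mesh_io.load_mesh(row["whole_mesh"])
        mat = target.vertex_material
        if mat is None:
            mat = transfer_material(target, mesh_io.load_mesh(row["enamel_mesh"]))
        try:
            rec_t = measure_instance(
                ShapeVector.from_mesh_arrays(target.vertices, mat), target.faces)
        except ToothSSMError:
            continue
        rec_r = state["measurements"].set_index("id").loc[str(row["id"])]
        for name in MEASUREMENT_NAMES[:6]:
            reg_meas.append(float(rec_r[name]))
            tgt_meas.append(getattr(rec_t, name))
    ba = bland_altman(reg_meas, tgt_meas)
    with open(os.path.join(sdir, "bland_altman.json"), "w") as fh:
        json.dump({"bias": ba.bias, "sd": ba.sd, "lower": ba.lower,
                   "upper": ba.upper, "n": len(reg_meas)}, fh, indent=1)
    log.info("stats -> %s", sdir)


_STAGE_FUNCS = {
    "synth": stage_synth, "align": stage_align, "register": stage_register,
    "fit": stage_fit, "sweep": stage_sweep, "cej": stage_cej,
    "landmarks": stage_landmarks, "measure": stage_measure, "stats": stage_stats,
}


def run_pipeline(config: PipelineConfig, stages=None) -> PipelineReport:
    """Run the requested stages in canonical order (all of them by default;
    'synth' is skipped when an external manifest is configured)."""
    os.makedirs(config.outdir, exist_ok=True)
    if stages is None:
        stages = [s for s in STAGES if not (s == "synth" and config.manifest)]
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise InvalidInputError(f"unknown stage(s): {bad}")
    stages = sorted(set(stages), key=STAGES.index)
    state: dict = {}
    report = PipelineReport()
    for stage in stages:
        try:
            _STAGE_FUNCS[stage](config, state)
        except ToothSSMError as exc:
            raise ToothSSMError(
                f"pipeline halted at stage {stage!r}: {exc}; "
                f"completed stages: {report.completed}") from exc
        report.completed.append(stage)
    report.artifacts["outdir"] = config.outdir
    return report
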