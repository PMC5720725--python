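"""Automated anatomical landmarks and inter-landmark measurements.

All criteria operate in the model frame (+x mesial, +y labial,
+z incisal) with half-partition planes through the whole-mesh vertex
centroid. Crown-maximum landmarks are restricted to enamel-labelled
nodes and CEJ landmarks to nodes of the extracted CEJ curve. Ties break
toward the lowest vertex index.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cej import CEJCurve, binarize, elements_from_nodes, extract_cej, nodes_from_elements, smooth_materials
from .cohort import ShapeVector
from .errors import InvalidInputError, LandmarkError
from .mesh import SurfaceMesh, build_adjacency, enclosed_volume, surface_area
from .model import PCWeights, ShapeModel, generate_instance

__all__ = ["LandmarkSet", "MeasurementRecord", "detect_landmarks", "measure",
           "measure_sweep", "MEASUREMENT_NAMES", "LANDMARK_NAMES"]

LANDMARK_NAMES = ("RA", "CEJtLa", "CEJtLi", "CEJpM", "CEJpD",
                  "CmM", "CmD", "CmLa", "CmLi", "CmIE")
MEASUREMENT_NAMES = ("LDCc", "LDC", "MDCc", "MDC", "LORla", "LOCla", "vol", "area")


@dataclass
class LandmarkSet:
    points: dict          # name -> (3,) coordinates, mm
    indices: dict         # name -> source vertex index

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def complete(self) -> bool:
        return all(n in self.points for n in LANDMARK_NAMES)


@dataclass
class MeasurementRecord:
    LDCc: float
    LDC: float
    MDCc: float
    MDC: float
    LORla: float
    LOCla: float
    vol: float | None = None
    area: float | None = None

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in MEASUREMENT_NAMES}

    def linear_values(self) -> dict:
        return {n: getattr(self, n) for n in MEASUREMENT_NAMES[:6]}


def _argext(mask: np.ndarray, key: np.ndarray, maximise: bool, name: str) -> int:
    idx = np.where(mask)[0]
    if idx.size == 0:
        raise LandmarkError(f"no candidate nodes for landmark {name}", landmark=name)
    vals = key[idx]
    best = vals.max() if maximise else vals.min()
    # lowest vertex index among exact ties
    return int(idx[vals == best].min())


def detect_landmarks(mesh: SurfaceMesh, node_materials: np.ndarray,
                     cej: CEJCurve) -> LandmarkSet:
    """Identify the 10 landmarks from geometry, material and the CEJ curve.

    CEJ landmarks are drawn from the largest extracted loop; crown maxima
    from enamel nodes; RA is the global z-minimum.
    """
    node_materials = np.asarray(node_materials, dtype=np.float64)
    if len(node_materials) != mesh.n_vertices:
        raise InvalidInputError("node material length must match vertex count")
    v = mesh.vertices
    centroid = mesh.centroid()
    enamel = node_materials >= 0.5
    if not enamel.any():
        raise LandmarkError("no enamel nodes: crown landmarks undefined")
    if cej.n_loops == 0:
        raise LandmarkError("no CEJ loop: CEJ landmarks undefined")
    cej_nodes = np.zeros(mesh.n_vertices, dtype=bool)
    cej_nodes[np.asarray(cej.loops[0], dtype=np.int64)] = True

    all_nodes = np.ones(mesh.n_vertices, dtype=bool)
    labial = v[:, 1] > centroid[1]
    lingual = v[:, 1] < centroid[1]
    mesial = v[:, 0] > centroid[0]
    distal = v[:, 0] < centroid[0]

    idx = {
        "RA": _argext(all_nodes, v[:, 2], False, "RA"),
        "CmIE": _argext(enamel, v[:, 2], True, "CmIE"),
        "CmM": _argext(enamel, v[:, 0], True, "CmM"),
        "CmD": _argext(enamel, v[:, 0], False, "CmD"),
        "CmLa": _argext(enamel, v[:, 1], True, "CmLa"),
        "CmLi": _argext(enamel, v[:, 1], False, "CmLi"),
        "CEJtLa": _argext(cej_nodes & labial, v[:, 2], False, "CEJtLa"),
        "CEJtLi": _argext(cej_nodes & lingual, v[:, 2], False, "CEJtLi"),
        "CEJpM": _argext(cej_nodes & mesial, v[:, 2], True, "CEJpM"),
        "CEJpD": _argext(cej_nodes & distal, v[:, 2], True, "CEJpD"),
    }
    return LandmarkSet(points={k: v[i].copy() for k, i in idx.items()}, indices=idx)


def measure(landmarks: LandmarkSet, mesh: SurfaceMesh) -> MeasurementRecord:
    """Euclidean inter-landmark distances plus surface area and (for closed
    meshes) enclosed volume."""
    if not landmarks.complete():
        missing = [n for n in LANDMARK_NAMES if n not in landmarks.points]
        raise InvalidInputError(f"landmark set incomplete: missing {missing}")

    def dist(a: str, b: str) -> float:
        return float(np.linalg.norm(landmarks[a] - landmarks[b]))

    vol = None
    if mesh.is_closed():
        vol = enclosed_volume(mesh)
    else:
        warnings.warn("open mesh: volume omitted from measurements")
    return MeasurementRecord(
        LDCc=dist("CEJtLa", "CEJtLi"),
        LDC=dist("CmLa", "CmLi"),
        MDCc=dist("CEJpM", "CEJpD"),
        MDC=dist("CmM", "CmD"),
        LORla=dist("RA", "CEJtLa"),
        LOCla=dist("CEJtLa", "CmIE"),
        vol=vol,
        area=surface_area(mesh),
    )


def measure_instance(vec: ShapeVector, faces: np.ndarray,
                     smoothing_max_iter: int = 100) -> MeasurementRecord:
    """Full measurement chain for one material-carrying shape vector:
    binarise -> element majority -> smooth -> CEJ -> landmarks -> measure."""
    if not vec.has_material:
        raise InvalidInputError("instance carries no material values")
    mesh = SurfaceMesh(vec.coords(), faces)
    ih = binarize(np.clip(vec.materials(), 0.0, 1.0))
    adjacency = build_adjacency(mesh)
    elem = elements_from_nodes(mesh, ih)
    elem, _, _ = smooth_materials(mesh, elem, max_iter=smoothing_max_iter,
                                  adjacency=adjacency)
    nodes = nodes_from_elements(mesh, elem)
    cej = extract_cej(mesh, elem)
    lms = detect_landmarks(mesh, nodes, cej)
    return measure(lms, mesh)


def measure_sweep(model: ShapeModel, faces: np.ndarray, pc: int,
                  levels=(-3, -2, -1, 0, 1, 2, 3)) -> list[dict]:
    """Measurements of sigma-sweep instances of one PC; the table feeding
    the per-PC regression analysis.

    Returns one row per level: ``{"level", "pc", measurements..., "error"}``
    with ``error`` set (and measurements None) where landmarking failed.
    """
    rows = []
    for level in levels:
        w = np.zeros(pc)
        w[pc - 1] = level
        vec = generate_instance(model, PCWeights(w, sigma_units=True), c=pc)
        row: dict = {"pc": pc, "level": float(level), "error": None}
        try:
            rec = measure_instance(vec, faces)
            row.update(rec.as_dict())
        except (LandmarkError, InvalidInputError) as exc:
            row["error"] = str(exc)
            row.update({n: None for n in MEASUREMENT_NAMES})
        rows.append(row)
    return rows
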