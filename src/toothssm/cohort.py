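"""Flattened shape vectors and registered cohorts.

A shape vector lists nodal variables in node-interleaved order:
``[x1, y1, z1, (I1), ..., xM, yM, zM, (IM)]`` where ``I`` is the binary
enamel (1) / dentin (0) surface material identifier.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass
class ShapeVector:
    values: np.ndarray
    has_material: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        stride = 4 if self.has_material else 3
        if len(self.values) % stride != 0:
            raise InvalidInputError(
                f"vector length {len(self.values)} not a multiple of {stride}")

    @property
    def n_nodes(self) -> int:
        return len(self.values) // (4 if self.has_material else 3)

    def coords(self) -> np.ndarray:
        """Nodal coordinates as an (M, 3) array."""
        if self.has_material:
            return self.values.reshape(-1, 4)[:, :3]
        return self.values.reshape(-1, 3)

    def materials(self) -> np.ndarray | None:
        if not self.has_material:
            return None
        return self.values.reshape(-1, 4)[:, 3]

    @classmethod
    def from_mesh_arrays(cls, vertices: np.ndarray,
                         material: np.ndarray | None = None) -> "ShapeVector":
        vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        if material is None:
            return cls(vertices.ravel(), has_material=False)
        material = np.asarray(material, dtype=np.float64).ravel()
        if len(material) != len(vertices):
            raise InvalidInputError("material length must match vertex count")
        packed = np.column_stack([vertices, material]).ravel()
        return cls(packed, has_material=True)


@dataclass
class RegisteredCohort:
    """Specimens in point-to-point correspondence on shared connectivity."""

    faces: np.ndarray
    vectors: list[ShapeVector]
    ids: list[str]
    groups: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not (len(self.vectors) == len(self.ids) == len(self.groups)):
            raise InvalidInputError("vectors, ids and groups must have equal lengths")
        if self.vectors:
            m = self.vectors[0].n_nodes
            flag = self.vectors[0].has_material
            for v in self.vectors:
                if v.n_nodes != m or v.has_material != flag:
                    raise InvalidInputError("all shape vectors must share M and material flag")
            if self.faces.size and self.faces.max() >= m:
                raise InvalidInputError("faces reference node indices beyond M")

    @property
    def n_specimens(self) -> int:
        return len(self.vectors)

    @property
    def n_nodes(self) -> int:
        return self.vectors[0].n_nodes if self.vectors else 0

    @property
    def has_material(self) -> bool:
        return bool(self.vectors) and self.vectors[0].has_material

    def matrix(self) -> np.ndarray:
        """(N, V) data matrix, one flattened specimen per row."""
        return np.vstack([v.values for v in self.vectors])
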