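"""Analytic test solids: unit cube and icosphere."""
from __future__ import annotations

import numpy as np

from .mesh import SurfaceMesh, clean_mesh, signed_volume


def make_cube(side: float = 1.0, center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Axis-aligned closed cube, 8 vertices / 12 triangles, outward wound."""
    c = np.asarray(center, dtype=np.float64)
    h = side / 2.0
    corners = np.array([
        [-h, -h, -h], [h, -h, -h], [h, h, -h], [-h, h, -h],
        [-h, -h, h], [h, -h, h], [h, h, h], [-h, h, h],
    ]) + c
    quads = [
        (0, 3, 2, 1),  # bottom (-z)
        (4, 5, 6, 7),  # top (+z)
        (0, 1, 5, 4),  # -y
        (2, 3, 7, 6),  # +y
        (1, 2, 6, 5),  # +x
        (3, 0, 4, 7),  # -x
    ]
    faces = []
    for a, b, cc, d in quads:
        faces.append((a, b, cc))
        faces.append((a, cc, d))
    return SurfaceMesh(corners, np.asarray(faces, dtype=np.int64))


def make_icosphere(radius: float = 1.0, subdivisions: int = 2,
                   center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Closed icosphere via repeated midpoint subdivision of an icosahedron."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=np.float64)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    for _ in range(subdivisions):
        verts_list = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                m = verts_list[a] + verts_list[b]
                m = m / np.linalg.norm(m)
                midpoint[key] = len(verts_list)
                verts_list.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=np.int64)
    mesh = SurfaceMesh(verts * radius + np.asarray(center, dtype=np.float64), faces)
    if signed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


def make_uv_sphere(radius: float = 1.0, n_theta: int = 32, n_phi: int = 17,
                   center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Closed latitude/longitude sphere. With odd ``n_phi`` a vertex ring
    lies exactly on the equator (z = 0)."""
    phis = np.linspace(np.pi / 2, -np.pi / 2, n_phi)[1:-1]  # exclude poles
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    verts = [np.array([0.0, 0.0, radius])]
    for phi in phis:
        ring = np.column_stack([
            radius * np.cos(phi) * np.cos(theta),
            radius * np.cos(phi) * np.sin(theta),
            np.full(n_theta, radius * np.sin(phi)),
        ])
        verts.append(ring)
    verts.append(np.array([0.0, 0.0, -radius]))
    vertices = np.vstack([np.atleast_2d(v) for v in verts]) + np.asarray(center)
    n_rings = len(phis)
    bottom = 1 + n_rings * n_theta
    faces = []
    for k in range(n_theta):
        faces.append((0, 1 + k, 1 + (k + 1) % n_theta))
    for r in range(n_rings - 1):
        a = 1 + r * n_theta
        b = a + n_theta
        for k in range(n_theta):
            k1 = (k + 1) % n_theta
            faces.append((a + k, b + k, b + k1))
            faces.append((a + k, b + k1, a + k1))
    a = 1 + (n_rings - 1) * n_theta
    for k in range(n_theta):
        faces.append((a + k, bottom, a + (k + 1) % n_theta))
    mesh = SurfaceMesh(vertices, np.asarray(faces, dtype=np.int64))
    if signed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh
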