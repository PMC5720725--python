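"""Reading and writing of PLY (ASCII + binary little-endian), STL
(ASCII + binary) and OFF (ASCII) triangle meshes.

Per-vertex material labels are carried as a PLY vertex property named
``material`` (0/1) when present.
"""
from __future__ import annotations

import os
import struct

import numpy as np

from .errors import InvalidInputError, MeshFormatError
from .mesh import SurfaceMesh, clean_mesh

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def load_mesh(path: str, format: str | None = None) -> SurfaceMesh:
    """Load a surface mesh, inferring the format from the extension unless
    ``format`` (``"PLY" | "STL" | "OFF"``) is given.

    The mesh is cleaned on load: duplicate vertices are merged within
    1e-9 mm and degenerate faces dropped.
    """
    if not os.path.exists(path):
        raise MeshFormatError("file does not exist", path=path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt == "PLY":
        v, f, mat = _read_ply(path)
    elif fmt == "STL":
        v, f = _read_stl(path)
        mat = None
    elif fmt == "OFF":
        v, f = _read_off(path)
        mat = None
    else:
        raise MeshFormatError(f"unknown mesh format {fmt!r}", path=path)
    if len(v) == 0:
        raise InvalidInputError(f"mesh in {path} has no vertices")
    return clean_mesh(v, f, vertex_material=mat)


def save_mesh(mesh: SurfaceMesh, path: str, format: str | None = None) -> None:
    """Write a mesh; PLY output is ASCII and includes the ``material``
    vertex property if the mesh carries one."""
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt == "PLY":
        _write_ply(mesh, path)
    elif fmt == "STL":
        _write_stl(mesh, path)
    elif fmt == "OFF":
        _write_off(mesh, path)
    else:
        raise MeshFormatError(f"unknown mesh format {fmt!r}", path=path)


# ---------------------------------------------------------------- PLY

def _read_ply(path: str):
    with open(path, "rb") as fh:
        magic = fh.readline()
        if magic.strip() != b"ply":
            raise MeshFormatError("missing 'ply' magic", path=path, offset=0)
        fmt = None
        elements = []  # list of (name, count, [(prop_name, dtype or ('list', ct, it))])
        while True:
            offset = fh.tell()
            line = fh.readline()
            if not line:
                raise MeshFormatError("truncated header (no end_header)", path=path, offset=offset)
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise MeshFormatError("property before element", path=path, offset=offset)
                if tokens[1] == "list":
                    elements[-1][2].append((tokens[4], ("list", _PLY_TYPES[tokens[2]], _PLY_TYPES[tokens[3]])))
                else:
                    elements[-1][2].append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt is None:
            raise MeshFormatError("missing format line", path=path)
        if fmt == "ascii":
            data = _read_ply_ascii(fh, elements, path)
        elif fmt == "binary_little_endian":
            data = _read_ply_binary(fh, elements, path, "<")
        elif fmt == "binary_big_endian":
            data = _read_ply_binary(fh, elements, path, ">")
        else:
            raise MeshFormatError(f"unsupported PLY format {fmt!r}", path=path)
    if "vertex" not in data:
        raise MeshFormatError("no vertex element", path=path)
    vdata = data["vertex"]
    try:
        v = np.column_stack([vdata["x"], vdata["y"], vdata["z"]])
    except KeyError as exc:
        raise MeshFormatError(f"vertex element missing coordinate {exc}", path=path)
    mat = np.asarray(vdata["material"], dtype=np.float64) if "material" in vdata else None
    faces = []
    fdata = data.get("face", {})
    for poly in fdata.get("vertex_indices", fdata.get("vertex_index", [])):
        poly = list(poly)
        for k in range(1, len(poly) - 1):  # fan-triangulate polygons
            faces.append((poly[0], poly[k], poly[k + 1]))
    f = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    return np.asarray(v, dtype=np.float64), f, mat


def _read_ply_ascii(fh, elements, path):
    data = {}
    for name, count, props in elements:
        cols = {p: [] for p, _ in props}
        for _ in range(count):
            offset = fh.tell()
            line = fh.readline()
            if not line:
                raise MeshFormatError(f"truncated {name} data", path=path, offset=offset)
            tokens = line.split()
            pos = 0
            try:
                for pname, ptype in props:
                    if isinstance(ptype, tuple):
                        n = int(tokens[pos]); pos += 1
                        cols[pname].append([int(float(t)) for t in tokens[pos:pos + n]])
                        pos += n
                    else:
                        val = float(tokens[pos]); pos += 1
                        cols[pname].append(val)
            except (IndexError, ValueError):
                raise MeshFormatError(f"malformed {name} row", path=path, offset=offset)
        data[name] = cols
    return data


def _read_ply_binary(fh, elements, path, endian):
    data = {}
    for name, count, props in elements:
        cols = {p: [] for p, _ in props}
        fixed = all(not isinstance(pt, tuple) for _, pt in props)
        if fixed:
            dt = np.dtype([(p, endian + t) for p, t in props])
            offset = fh.tell()
            buf = fh.read(dt.itemsize * count)
            if len(buf) != dt.itemsize * count:
                raise MeshFormatError(f"truncated {name} data", path=path, offset=offset)
            arr = np.frombuffer(buf, dtype=dt)
            for p, _ in props:
                cols[p] = np.asarray(arr[p], dtype=np.float64)
        else:
            for _ in range(count):
                for pname, ptype in props:
                    offset = fh.tell()
                    if isinstance(ptype, tuple):
                        _, ct, it = ptype
                        ct_size = int(ct[1])
                        buf = fh.read(ct_size)
                        if len(buf) != ct_size:
                            raise MeshFormatError(f"truncated {name} list count", path=path, offset=offset)
                        n = int(np.frombuffer(buf, dtype=endian + ct)[0])
                        it_size = int(it[1])
                        buf = fh.read(it_size * n)
                        if len(buf) != it_size * n:
                            raise MeshFormatError(f"truncated {name} list data", path=path, offset=offset)
                        cols[pname].append(np.frombuffer(buf, dtype=endian + it).astype(np.int64))
                    else:
                        size = int(ptype[1])
                        buf = fh.read(size)
                        if len(buf) != size:
                            raise MeshFormatError(f"truncated {name} data", path=path, offset=offset)
                        cols[pname].append(float(np.frombuffer(buf, dtype=endian + ptype)[0]))
        data[name] = cols
    return data


def _write_ply(mesh: SurfaceMesh, path: str) -> None:
    has_mat = mesh.vertex_material is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if has_mat:
            fh.write("property double material\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for i, (x, y, z) in enumerate(mesh.vertices):
            row = f"{x:.12g} {y:.12g} {z:.12g}"
            if has_mat:
                row += f" {mesh.vertex_material[i]:.12g}"
            fh.write(row + "\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


# ---------------------------------------------------------------- STL

def _read_stl(path: str):
    with open(path, "rb") as fh:
        head = fh.read(5)
    if head.startswith(b"solid"):
        try:
            return _read_stl_ascii(path)
        except MeshFormatError:
            pass  # some binary STLs start with "solid"; fall through
    return _read_stl_binary(path)


def _read_stl_ascii(path: str):
    verts = []
    with open(path, "rb") as fh:
        n_facet_open = 0
        while True:
            offset = fh.tell()
            line = fh.readline()
            if not line:
                break
            tokens = line.split()
            if not tokens:
                continue
            kw = tokens[0].lower()
            if kw == b"vertex":
                if len(tokens) != 4:
                    raise MeshFormatError("malformed STL vertex line", path=path, offset=offset)
                try:
                    verts.append([float(t) for t in tokens[1:4]])
                except ValueError:
                    raise MeshFormatError("non-numeric STL vertex", path=path, offset=offset)
            elif kw == b"facet":
                n_facet_open += 1
            elif kw == b"endfacet":
                n_facet_open -= 1
    if len(verts) == 0 or len(verts) % 3 != 0:
        raise MeshFormatError(f"STL vertex count {len(verts)} not a multiple of 3", path=path)
    v = np.asarray(verts, dtype=np.float64)
    f = np.arange(len(verts), dtype=np.int64).reshape(-1, 3)
    return v, f


def _read_stl_binary(path: str):
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        fh.seek(80)
        buf = fh.read(4)
        if len(buf) != 4:
            raise MeshFormatError("truncated binary STL header", path=path, offset=80)
        (n,) = struct.unpack("<I", buf)
        if size != 84 + 50 * n:
            raise MeshFormatError(
                f"binary STL size {size} does not match {n} triangles", path=path, offset=80)
        rec = np.dtype([("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")])
        arr = np.frombuffer(fh.read(50 * n), dtype=rec)
    v = arr["verts"].reshape(-1, 3).astype(np.float64)
    f = np.arange(3 * n, dtype=np.int64).reshape(-1, 3)
    return v, f


def _write_stl(mesh: SurfaceMesh, path: str) -> None:
    normals = mesh.face_normals()
    with open(path, "w") as fh:
        fh.write("solid toothssm\n")
        for fi, (a, b, c) in enumerate(mesh.faces):
            n = normals[fi]
            fh.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
            fh.write("    outer loop\n")
            for vi in (a, b, c):
                x, y, z = mesh.vertices[vi]
                fh.write(f"      vertex {x:.9g} {y:.9g} {z:.9g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid toothssm\n")


# ---------------------------------------------------------------- OFF

def _read_off(path: str):
    with open(path, "rb") as fh:
        tokens: list[bytes] = []
        offsets: list[int] = []
        while True:
            offset = fh.tell()
            line = fh.readline()
            if not line:
                break
            body = line.split(b"#", 1)[0]
            for t in body.split():
                tokens.append(t)
                offsets.append(offset)
    if not tokens or tokens[0] != b"OFF":
        raise MeshFormatError("missing OFF magic", path=path, offset=0)
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # skip edge count
        v = np.array([[float(tokens[pos + 3 * i + k]) for k in range(3)] for i in range(nv)])
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            n = int(tokens[pos]); pos += 1
            poly = [int(tokens[pos + k]) for k in range(n)]
            pos += n
            for k in range(1, n - 1):
                faces.append((poly[0], poly[k], poly[k + 1]))
    except (IndexError, ValueError):
        off = offsets[min(pos, len(offsets) - 1)] if offsets else 0
        raise MeshFormatError("malformed OFF data", path=path, offset=off)
    return v, np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _write_off(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")
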