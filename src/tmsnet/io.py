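"""Interchange formats: PLY meshes, per-vertex TSV metrics, time-series
matrices, and optional GIFTI readers.

All text formats use ``%.17g`` for floats so that a write/read round trip is
bit-exact, which the stage-composition determinism contract relies on.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .surface import ParcellationMap, SurfaceMesh
from .fmri import TimeSeriesMatrix

__all__ = [
    "write_ply",
    "read_ply",
    "write_vertex_metric",
    "read_vertex_metric",
    "write_parcellation",
    "read_parcellation",
    "write_timeseries",
    "read_timeseries",
    "read_gifti_surface",
    "read_gifti_labels",
]

FLOAT_FMT = "%.17g"


def write_ply(mesh: SurfaceMesh, path: str | Path, binary: bool = False) -> None:
    """Write a mesh as PLY (ASCII by default, binary little-endian on request)
    with per-vertex normals."""
    path = Path(path)
    v, f, n = mesh.vertices, mesh.faces, mesh.normals
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        "comment tmsnet synthetic cortical patch\n"
        f"element vertex {v.shape[0]}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "property double nx\nproperty double ny\nproperty double nz\n"
        f"element face {f.shape[0]}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        vn = np.hstack([v, n])
        if binary:
            fh.write(vn.astype("<f8").tobytes())
            for tri in f:
                fh.write(struct.pack("<Biii", 3, *tri))
        else:
            for row in vn:
                fh.write((" ".join(FLOAT_FMT % x for x in row) + "\n").encode())
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n".encode())


_PLY_SCALARS = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def read_ply(path: str | Path) -> SurfaceMesh:
    """Read an ASCII or binary little-endian PLY mesh.

    Vertex x/y/z (and nx/ny/nz if present) are used; other properties are
    skipped.  Normals are recomputed when absent from the file.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise InputError(f"{path} is not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list]] = []
        while True:
            line = fh.readline()
            if not line:
                raise InputError("unexpected end of PLY header")
            tok = line.decode("ascii", "replace").split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if tok[1] == "list":
                    elements[-1][2].append(("list", tok[2], tok[3], tok[4]))
                else:
                    elements[-1][2].append(("scalar", tok[1], tok[2]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise InputError(f"unsupported PLY format {fmt!r}")
        data = {}
        for name, count, props in elements:
            data[name] = _read_ply_element(fh, fmt, count, props)

    if "vertex" not in data or "face" not in data:
        raise InputError("PLY file must contain vertex and face elements")
    vert = data["vertex"]
    vertices = np.column_stack([vert["x"], vert["y"], vert["z"]])
    faces = np.asarray(data["face"]["vertex_indices"], dtype=np.int64)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise InputError("only triangulated PLY meshes are supported")
    if all(k in vert for k in ("nx", "ny", "nz")):
        normals = np.column_stack([vert["nx"], vert["ny"], vert["nz"]])
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = normals / np.where(norms > 0, norms, 1.0)
    else:
        from .surface import _vertex_normals

        normals = _vertex_normals(vertices, faces)
    return SurfaceMesh(vertices, faces, normals)


def _read_ply_element(fh, fmt: str, count: int, props: list) -> dict:
    names = [p[2] if p[0] == "scalar" else p[3] for p in props]
    out: dict[str, list] = {n: [] for n in names}
    if fmt == "ascii":
        for _ in range(count):
            tok = fh.readline().split()
            i = 0
            for p in props:
                if p[0] == "scalar":
                    out[p[2]].append(float(tok[i]))
                    i += 1
                else:
                    n = int(tok[i])
                    out[p[3]].append([int(x) for x in tok[i + 1 : i + 1 + n]])
                    i += 1 + n
    else:
        for _ in range(count):
            for p in props:
                if p[0] == "scalar":
                    dt = np.dtype("<" + _PLY_SCALARS[p[1]])
                    (val,) = np.frombuffer(fh.read(dt.itemsize), dt)
                    out[p[2]].append(float(val))
                else:
                    cdt = np.dtype("<" + _PLY_SCALARS[p[1]])
                    (n,) = np.frombuffer(fh.read(cdt.itemsize), cdt)
                    idt = np.dtype("<" + _PLY_SCALARS[p[2]])
                    vals = np.frombuffer(fh.read(idt.itemsize * int(n)), idt)
                    out[p[3]].append(vals.astype(np.int64).tolist())
    return {k: (v if k == "vertex_indices" else np.asarray(v, float)) for k, v in out.items()}


def write_vertex_metric(
    values: np.ndarray, path: str | Path, column: str = "value"
) -> None:
    """Per-vertex scalar TSV with header (vertex_index, <column>)."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write(f"vertex_index\t{column}\n")
        for i, v in enumerate(values):
            fh.write(f"{i}\t{FLOAT_FMT % v}\n")


def read_vertex_metric(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "vertex_index" not in df.columns or df.shape[1] < 2:
        raise InputError(f"{path} is not a vertex metric TSV")
    df = df.sort_values("vertex_index")
    return df[df.columns[1]].to_numpy(dtype=float)


def write_parcellation(parcellation: ParcellationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("vertex_index\tlabel\n")
        for i, lab in enumerate(parcellation.labels):
            fh.write(f"{i}\t{lab}\n")


def read_parcellation(path: str | Path) -> ParcellationMap:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["vertex_index", "label"]:
        raise InputError(f"{path} is not a parcellation TSV")
    df = df.sort_values("vertex_index")
    return ParcellationMap(df["label"].to_numpy(dtype=np.int64))


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    """Vertex x time matrix as TSV; the TR is recorded in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# tr_seconds={FLOAT_FMT % ts.tr}\n")
        np.savetxt(fh, ts.data, fmt=FLOAT_FMT, delimiter="\t")


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# tr_seconds="):
            raise InputError(f"{path} lacks the tr_seconds header")
        tr = float(first.split("=", 1)[1])
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return TimeSeriesMatrix(data, tr)


def read_gifti_surface(path: str | Path) -> SurfaceMesh:
    """Optional GIFTI surface (.surf.gii) reader; requires nibabel."""
    import nibabel as nib

    img = nib.load(str(path))
    vertices = faces = None
    for arr in img.darrays:
        code = arr.intent
        if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            vertices = np.asarray(arr.data, dtype=np.float64)
        elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(arr.data, dtype=np.int64)
    if vertices is None or faces is None:
        raise InputError(f"{path} lacks pointset/triangle arrays")
    from .surface import _vertex_normals

    return SurfaceMesh(vertices, faces, _vertex_normals(vertices, faces))


def read_gifti_labels(path: str | Path) -> ParcellationMap:
    """Optional GIFTI label (.label.gii) reader; requires nibabel."""
    import nibabel as nib

    img = nib.load(str(path))
    if not img.darrays:
        raise InputError(f"{path} contains no data arrays")
    return ParcellationMap(np.asarray(img.darrays[0].data, dtype=np.int64))
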