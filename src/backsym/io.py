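"""Point-cloud file I/O: PLY (ASCII and binary little-endian) and PCD (ASCII).

Only the vertex element is interpreted: properties ``x, y, z`` are mandatory,
``nx, ny, nz`` optional, plus an optional per-vertex scalar (written as
``quality``) used for deviation colormaps.  Coordinates are millimetres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import PointCloud

__all__ = ["read_point_cloud", "write_point_cloud", "read_ply", "write_ply", "read_pcd", "write_pcd"]

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4", "float64": "<f8", "double": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "ushort": "<u2", "int": "<i4", "int32": "<i4",
    "uint": "<u4", "uint32": "<u4",
}


def read_point_cloud(path) -> PointCloud:
    """Read a PLY or PCD file by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return read_ply(path)
    if suffix == ".pcd":
        return read_pcd(path)
    raise ValueError(f"unsupported point-cloud format: {path.suffix!r}")


def write_point_cloud(path, cloud: PointCloud, scalars: np.ndarray | None = None) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        write_ply(path, cloud, scalars=scalars)
    elif suffix == ".pcd":
        write_pcd(path, cloud)
    else:
        raise ValueError(f"unsupported point-cloud format: {path.suffix!r}")


def read_ply(path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError("not a PLY file")
        fmt = None
        names: list[str] = []
        dtypes: list[str] = []
        count = 0
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    count = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError("list properties unsupported on vertex element")
                dtypes.append(_PLY_DTYPES[tokens[1]])
                names.append(tokens[2])
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"unsupported PLY format {fmt!r}")
        for axis in "xyz":
            if axis not in names:
                raise ValueError(f"PLY vertex element lacks property {axis!r}")
        dtype = np.dtype(list(zip(names, dtypes)))
        if fmt == "ascii":
            rows = np.loadtxt(fh, dtype=np.float64, max_rows=count, ndmin=2)
            data = {name: rows[:, k] for k, name in enumerate(names)}
        else:
            raw = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
            data = {name: raw[name].astype(np.float64) for name in names}
    points = np.column_stack([data["x"], data["y"], data["z"]])
    normals = None
    if all(k in data for k in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]])
    return PointCloud(points=points, normals=normals)


def write_ply(path, cloud: PointCloud, scalars: np.ndarray | None = None) -> None:
    """Write an ASCII PLY point cloud; optional scalar goes out as ``quality``."""
    cols = [cloud.points]
    props = ["x", "y", "z"]
    if cloud.normals is not None:
        cols.append(cloud.normals)
        props += ["nx", "ny", "nz"]
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=np.float64).reshape(len(cloud), 1)
        cols.append(scalars)
        props.append("quality")
    table = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        for name in props:
            fh.write(f"property float {name}\n")
        fh.write("end_header\n")
        np.savetxt(fh, table, fmt="%.6f")


def read_pcd(path) -> PointCloud:
    header: dict[str, list[str]] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline().decode("ascii", "replace").strip()
            if not line:
                raise ValueError("truncated PCD header")
            if line.startswith("#"):
                continue
            key, *vals = line.split()
            header[key] = vals
            if key == "DATA":
                break
        if header["DATA"][0] != "ascii":
            raise ValueError("only ASCII PCD is supported")
        fields = header["FIELDS"]
        count = int(header["POINTS"][0])
        rows = np.loadtxt(fh, dtype=np.float64, max_rows=count, ndmin=2)
    data = {name: rows[:, k] for k, name in enumerate(fields)}
    points = np.column_stack([data["x"], data["y"], data["z"]])
    normals = None
    if all(k in data for k in ("normal_x", "normal_y", "normal_z")):
        normals = np.column_stack([data["normal_x"], data["normal_y"], data["normal_z"]])
    return PointCloud(points=points, normals=normals)


def write_pcd(path, cloud: PointCloud) -> None:
    has_normals = cloud.normals is not None
    fields = ["x", "y", "z"] + (["normal_x", "normal_y", "normal_z"] if has_normals else [])
    table = np.column_stack([cloud.points] + ([cloud.normals] if has_normals else []))
    n = len(cloud)
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\nVERSION 0.7\n")
        fh.write(f"FIELDS {' '.join(fields)}\n")
        fh.write(f"SIZE {' '.join(['4'] * len(fields))}\n")
        fh.write(f"TYPE {' '.join(['F'] * len(fields))}\n")
        fh.write(f"COUNT {' '.join(['1'] * len(fields))}\n")
        fh.write(f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n")
        np.savetxt(fh, table, fmt="%.6f")


def dump_json(path, payload: dict) -> None:
    """Write a JSON diagnostics/result file with stable formatting."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
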