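"""Minimal MetaImage (.mhd/.raw) and CSV grid I/O.

Only the subset of the MetaImage header needed for scalar voxel grids is
supported: 3-D, local raw file, little-endian float32/float64.  World
coordinates are mm with a voxel-corner origin.
"""

from __future__ import annotations

import os

import numpy as np

__all__ = ["write_mhd", "read_mhd", "write_curve_csv", "read_curve_csv"]

_MET_TYPES = {"MET_FLOAT": np.float32, "MET_DOUBLE": np.float64}
_NP_TYPES = {np.dtype(np.float32): "MET_FLOAT", np.dtype(np.float64): "MET_DOUBLE"}


def write_mhd(path: str, array: np.ndarray, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> None:
    """Write a 3-D scalar grid as MetaImage header + raw pair.

    The array uses (i, j, k) = (x, y, z) index order; the raw file is
    written in the MetaImage convention (x fastest).
    """
    if array.ndim != 3:
        raise ValueError("expected a 3-D array")
    arr = np.asarray(array)
    if arr.dtype not in _NP_TYPES:
        arr = arr.astype(np.float64)
    base, _ = os.path.splitext(path)
    raw_name = os.path.basename(base) + ".raw"
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        f"DimSize = {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
        f"ElementSpacing = {spacing_mm[0]} {spacing_mm[1]} {spacing_mm[2]}",
        f"Offset = {origin_mm[0]} {origin_mm[1]} {origin_mm[2]}",
        f"ElementType = {_NP_TYPES[arr.dtype]}",
        f"ElementDataFile = {raw_name}",
    ]
    with open(base + ".mhd", "w") as fh:
        fh.write("\n".join(header) + "\n")
    # MetaImage raw order: x fastest -> transpose to (z, y, x) C-order
    arr.transpose(2, 1, 0).tofile(base + ".raw")


def read_mhd(path: str):
    """Read a MetaImage pair; returns (array[i,j,k], spacing, origin)."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    dims = tuple(int(v) for v in meta["DimSize"].split())
    spacing = tuple(float(v) for v in meta["ElementSpacing"].split())
    origin = tuple(float(v) for v in meta.get("Offset", "0 0 0").split())
    dtype = _MET_TYPES[meta["ElementType"]]
    raw_path = os.path.join(os.path.dirname(path), meta["ElementDataFile"])
    flat = np.fromfile(raw_path, dtype=dtype)
    arr = flat.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    return arr, spacing, origin


def write_curve_csv(path: str, columns: dict, header_comment: str = "") -> None:
    """Write named 1-D columns as CSV with full-precision floats."""
    keys = list(columns)
    n = len(next(iter(columns.values())))
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(",".join(keys) + "\n")
        for i in range(n):
            fh.write(",".join(repr(float(columns[k][i])) for k in keys) + "\n")


def read_curve_csv(path: str) -> dict:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    keys = lines[0].strip().split(",")
    data = np.array([[float(v) for v in ln.strip().split(",")] for ln in lines[1:]])
    return {k: data[:, i] for i, k in enumerate(keys)}
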