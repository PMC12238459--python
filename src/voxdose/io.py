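"""Grid I/O: MetaImage (.mhd/.raw) and .npy with a JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_mhd", "read_mhd", "write_npy_sidecar", "read_npy_sidecar"]

_MET_TYPES = {
    np.dtype(np.int16): "MET_SHORT",
    np.dtype(np.uint8): "MET_UCHAR",
    np.dtype(np.int32): "MET_INT",
    np.dtype(np.float32): "MET_FLOAT",
    np.dtype(np.float64): "MET_DOUBLE",
}
_NP_TYPES = {v: k for k, v in _MET_TYPES.items()}


def write_mhd(path, grid: np.ndarray, voxel_size_mm: float, origin_mm=(0.0, 0.0, 0.0)) -> Path:
    """Write a 3-D grid as an uncompressed MetaImage pair.

    Axis order in memory is (x, y, z); the raw file is written x-fastest
    as MetaImage expects, so the array is transposed on disk.
    """
    path = Path(path)
    if path.suffix != ".mhd":
        path = path.with_suffix(".mhd")
    raw = path.with_suffix(".raw")
    dtype = grid.dtype
    if dtype not in _MET_TYPES:
        grid = grid.astype(np.float64)
        dtype = grid.dtype
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {origin_mm[0]} {origin_mm[1]} {origin_mm[2]}",
        f"ElementSpacing = {voxel_size_mm} {voxel_size_mm} {voxel_size_mm}",
        f"DimSize = {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}",
        f"ElementType = {_MET_TYPES[dtype]}",
        f"ElementDataFile = {raw.name}",
    ]
    path.write_text("\n".join(header) + "\n")
    # x-fastest ordering: transpose to (z, y, x) then ravel C-style
    grid.transpose(2, 1, 0).tofile(raw)
    return path


def read_mhd(path):
    """Read an uncompressed MetaImage pair; returns (grid, voxel_size, origin)."""
    path = Path(path)
    meta = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    shape = tuple(int(v) for v in meta["DimSize"].split())
    spacing = [float(v) for v in meta["ElementSpacing"].split()]
    if len(set(spacing)) != 1:
        raise ValueError("only isotropic voxels are supported")
    origin = tuple(float(v) for v in meta.get("Offset", "0 0 0").split())
    dtype = _NP_TYPES[meta["ElementType"]]
    raw = path.parent / meta["ElementDataFile"]
    flat = np.fromfile(raw, dtype=dtype)
    grid = flat.reshape(shape[2], shape[1], shape[0]).transpose(2, 1, 0)
    return grid, spacing[0], origin


def write_npy_sidecar(path, grid: np.ndarray, voxel_size_mm: float, **meta) -> Path:
    """Write grid as .npy plus a JSON sidecar with spacing and metadata."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, grid)
    sidecar = {"voxel_size_mm": voxel_size_mm, "shape": list(grid.shape), **meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_npy_sidecar(path):
    path = Path(path)
    grid = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return grid, meta
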