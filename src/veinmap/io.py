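"""Readers and writers for every artifact the pipeline touches.

Formats: 16-bit grayscale TIFF/PNG for SWIR images and masks, 32-bit float
TIFF or whitespace-delimited text for depth/amplitude rasters, ascii PLY for
point clouds, CSV (header ``x1,y1,x2,y2``) for control-point pairs and JSON
for intrinsics / transforms.  All round-trips are lossless at the stated
precision.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import geometry
from .types import (
    CameraIntrinsics,
    ControlPointPairs,
    FormatError,
    LinearMap2D,
    SwirImage,
    TofFrame,
)

__all__ = [
    "read_swir",
    "write_swir",
    "read_tof",
    "make_tof_frame",
    "read_raster",
    "write_raster",
    "read_mask",
    "write_mask",
    "read_pairs",
    "write_pairs",
    "write_pointcloud",
    "read_pointcloud",
    "read_intrinsics",
    "write_intrinsics",
    "read_transform",
    "write_transform",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _read_gray(path: str | os.PathLike) -> np.ndarray:
    suffix = Path(path).suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    return arr


def read_swir(path: str | os.PathLike, bit_depth: int = 14) -> SwirImage:
    """Read a single-channel TIFF/PNG as a :class:`SwirImage` (bit-exact)."""
    return SwirImage(pixels=_read_gray(path), bit_depth=bit_depth)


def write_swir(img: SwirImage, path: str | os.PathLike) -> None:
    data = img.pixels.astype(np.uint16)
    suffix = Path(path).suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_raster(path: str | os.PathLike) -> np.ndarray:
    """Float raster from a 32-bit float TIFF or whitespace-delimited text."""
    suffix = Path(path).suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        return np.asarray(tifffile.imread(path), dtype=float)
    return np.loadtxt(path, dtype=float, ndmin=2)


def write_raster(arr: np.ndarray, path: str | os.PathLike) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    else:
        np.savetxt(path, np.asarray(arr, dtype=float))


def make_tof_frame(
    depth: np.ndarray,
    amplitude: np.ndarray,
    intrinsics: CameraIntrinsics,
    amplitude_floor: float = 0.0,
) -> TofFrame:
    """Assemble a :class:`TofFrame`, back-projecting each pixel to XYZ.

    The ray for pixel (row, col) is the undistorted normalized coordinate
    ``(x_n, y_n, 1)``; ``xyz = depth * ray`` (depth is the z-coordinate, mm).
    Pixels with non-positive depth or amplitude below ``amplitude_floor`` are
    flagged invalid — the screen for dropouts and flying pixels.
    """
    depth = np.asarray(depth, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if depth.shape != amplitude.shape:
        raise FormatError(
            f"depth {depth.shape} and amplitude {amplitude.shape} shapes differ"
        )
    rows, cols = np.mgrid[0 : depth.shape[0], 0 : depth.shape[1]]
    px = np.stack([cols.astype(float), rows.astype(float)], axis=-1)
    ray = geometry.undistort_point(geometry.normalize_pixel(px, intrinsics), intrinsics)
    xyz = np.empty(depth.shape + (3,), dtype=float)
    xyz[..., 0] = ray[..., 0] * depth
    xyz[..., 1] = ray[..., 1] * depth
    xyz[..., 2] = depth
    valid = (depth > 0) & (amplitude >= amplitude_floor)
    xyz[~valid] = 0.0
    return TofFrame(amplitude=amplitude, depth=depth, xyz=xyz, valid=valid)


def read_tof(
    depth_path: str | os.PathLike,
    amplitude_path: str | os.PathLike,
    intrinsics: CameraIntrinsics,
    amplitude_floor: float = 0.0,
) -> TofFrame:
    """Read depth + amplitude rasters and back-project to a TOF frame."""
    return make_tof_frame(
        read_raster(depth_path), read_raster(amplitude_path), intrinsics, amplitude_floor
    )


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Binary mask from an 8-bit PNG (non-zero → True)."""
    return _read_gray(path) > 0


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Binary mask as 8-bit PNG, 0/255."""
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_pairs(path: str | os.PathLike) -> ControlPointPairs:
    """Control-point pairs from a CSV with header ``x1,y1,x2,y2``."""
    with open(path) as fh:
        header = fh.readline().strip().replace(" ", "")
        if header.lower() != "x1,y1,x2,y2":
            raise FormatError(f"{path}: expected header 'x1,y1,x2,y2', got {header!r}")
        data = np.loadtxt(fh, delimiter=",", dtype=float, ndmin=2)
    if data.size == 0:
        return ControlPointPairs(np.empty((0, 2)), np.empty((0, 2)))
    if data.shape[1] != 4:
        raise FormatError(f"{path}: expected 4 columns, got {data.shape[1]}")
    return ControlPointPairs(data[:, 0:2], data[:, 2:4])


def write_pairs(pairs: ControlPointPairs, path: str | os.PathLike) -> None:
    data = np.hstack([pairs.x1, pairs.x2])
    np.savetxt(path, data, delimiter=",", header="x1,y1,x2,y2", comments="")


def write_pointcloud(
    points: np.ndarray,
    path: str | os.PathLike,
    labels: np.ndarray | None = None,
) -> None:
    """Write 3-D millimetre points to an ascii PLY file.

    Coordinates are stored as float32 vertex properties; an optional integer
    label per point is stored as a scalar ``label`` property."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.size and not np.isfinite(points).all():
        raise FormatError("point coordinates must be finite")
    if labels is not None:
        labels = np.asarray(labels, dtype=int).reshape(-1)
        if labels.shape[0] != points.shape[0]:
            raise FormatError("labels and points must have equal length")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {points.shape[0]}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if labels is not None:
            fh.write("property int label\n")
        fh.write("end_header\n")
        pts32 = points.astype(np.float32)
        for i in range(points.shape[0]):
            x, y, z = pts32[i]
            line = f"{x:.9g} {y:.9g} {z:.9g}"
            if labels is not None:
                line += f" {labels[i]}"
            fh.write(line + "\n")


def read_pointcloud(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ascii PLY written by :func:`write_pointcloud`.

    Returns ``(points, labels)``; labels is None if the file has no label
    property."""
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise FormatError(f"{path}: not a PLY file")
        n_vertices = None
        has_label = False
        for line in fh:
            line = line.strip()
            if line.startswith("element vertex"):
                n_vertices = int(line.split()[-1])
            elif line.startswith("property") and line.split()[-1] == "label":
                has_label = True
            elif line == "end_header":
                break
        if n_vertices is None:
            raise FormatError(f"{path}: missing vertex element")
        rows = [fh.readline().split() for _ in range(n_vertices)]
    if n_vertices == 0:
        return np.empty((0, 3)), (np.empty(0, dtype=int) if has_label else None)
    data = np.asarray(rows, dtype=float)
    points = data[:, :3]
    labels = data[:, 3].astype(int) if has_label else None
    return points, labels


def read_intrinsics(path: str | os.PathLike) -> CameraIntrinsics:
    with open(path) as fh:
        return CameraIntrinsics.from_dict(json.load(fh))


def write_intrinsics(intr: CameraIntrinsics, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(intr.to_dict(), fh, indent=2)


def read_transform(path: str | os.PathLike) -> LinearMap2D:
    with open(path) as fh:
        return LinearMap2D.from_dict(json.load(fh))


def write_transform(m: LinearMap2D, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(m.to_dict(), fh, indent=2)
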