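"""Shared container types for the vein detection / localization pipeline.

Coordinate conventions used throughout the package:

* Rasters are 2-D numpy arrays, row-major, row 0 at the top, column 0 at the
  left, with pixel centers at integer coordinates.
* A 2-D *point* is ``(x, y)`` where ``x`` is the column index and ``y`` the
  row index (both 0-based, possibly fractional).
* Depth and 3-D coordinates are in millimetres, expressed in the range
  camera's frame (z along the optical axis, positive in front of the camera).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np


class VeinmapError(Exception):
    """Base class for errors raised by this package."""


class FormatError(VeinmapError):
    """An input file or array violates the expected format."""


class RangeError(VeinmapError):
    """Pixel values exceed the declared bit depth."""


class DegenerateInputError(VeinmapError):
    """The input admits no meaningful answer (constant image, collinear
    control points, ...)."""


class RegistrationError(VeinmapError):
    """RANSAC or the distortion inversion failed to produce a transform."""


@dataclass
class SwirImage:
    """Single-channel SWIR reflectance raster.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Raw intensity counts. Integer typed.
    bit_depth : int
        A/D bit depth; all intensities must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 14

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"SWIR image must be single-channel 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise FormatError("SWIR image must be non-empty")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise RangeError(
                f"intensities outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TofFrame:
    """One frame from the time-of-flight range camera.

    ``amplitude`` (counts), ``depth`` (mm), per-pixel ``xyz`` (mm, camera
    frame; shape ``(rows, cols, 3)``) and a boolean ``valid`` flag share one
    pixel grid.  Where ``valid`` is set, ``depth > 0`` and ``xyz[..., 2] ==
    depth``; invalid pixels (dropouts, flying-pixel screens) carry no usable
    range sample.
    """

    amplitude: np.ndarray
    depth: np.ndarray
    xyz: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shape = self.depth.shape
        if self.amplitude.shape != shape or self.valid.shape != shape:
            raise FormatError("amplitude, depth and valid rasters must share one shape")
        if self.xyz.shape != shape + (3,):
            raise FormatError(f"xyz must have shape {shape + (3,)}, got {self.xyz.shape}")
        if self.valid.any():
            d = self.depth[self.valid]
            if not (d > 0).all():
                raise FormatError("depth must be positive wherever valid")
            z = self.xyz[self.valid][:, 2]
            if not np.allclose(z, d, rtol=1e-6, atol=0.0):
                raise FormatError("xyz z-component must equal depth wherever valid")

    @property
    def height(self) -> int:
        return self.depth.shape[0]

    @property
    def width(self) -> int:
        return self.depth.shape[1]


@dataclass
class ControlPointPairs:
    """Matched 2-D control points between the TOF frame (x1) and the SWIR
    frame (x2), stored as ``(N, 2)`` arrays of ``(x, y)`` pixel coordinates."""

    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float).reshape(-1, 2)
        self.x2 = np.asarray(self.x2, dtype=float).reshape(-1, 2)
        if self.x1.shape != self.x2.shape:
            raise FormatError("control point lists must have equal length")
        if not (np.isfinite(self.x1).all() and np.isfinite(self.x2).all()):
            raise FormatError("control points must be finite")

    def __len__(self) -> int:
        return self.x1.shape[0]

    def subset(self, idx) -> "ControlPointPairs":
        return ControlPointPairs(self.x1[idx], self.x2[idx])


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics with Brown radial distortion (k1, k2, k3).

    Focal lengths and the principal point are in pixels; the radial
    coefficients act on dimensionless normalized image coordinates."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise FormatError("focal lengths must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(**{k: float(d[k]) for k in ("fx", "fy", "cx", "cy")},
                   **{k: float(d.get(k, 0.0)) for k in ("k1", "k2", "k3")})


@dataclass
class LinearMap2D:
    """2-D linear map ``p2 = R @ p1 + T`` from TOF pixel coordinates into the
    SWIR pixel grid.

    ``R`` is a general invertible 2x2 matrix (it absorbs the scale change
    between the 176x144 and 636x508 grids as well as the rotation); ``T`` is
    in SWIR pixels.  When fitted by RANSAC, ``epsilon`` (inlier threshold in
    SWIR pixels), ``inliers`` (the consensus count f0) and ``seed`` record the
    provenance of the estimate."""

    R: np.ndarray
    T: np.ndarray
    epsilon: float | None = None
    inliers: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(2, 2)
        self.T = np.asarray(self.T, dtype=float).reshape(2)
        if abs(np.linalg.det(self.R)) < 1e-12:
            raise DegenerateInputError("R must be invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` (or ``(2,)``) points from frame F1 into frame F2."""
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.T

    def to_dict(self) -> dict:
        return {
            "R": self.R.tolist(),
            "T": self.T.tolist(),
            "epsilon": self.epsilon,
            "inliers": self.inliers,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearMap2D":
        return cls(
            R=np.asarray(d["R"], dtype=float),
            T=np.asarray(d["T"], dtype=float),
            epsilon=d.get("epsilon"),
            inliers=d.get("inliers"),
            seed=d.get("seed"),
        )


@dataclass
class RoiMasks:
    """Foreground segmentation plus the two edge-discarding ROI masks.

    ``mask_narrow`` discards a 10 px band at the background transition
    (background dilated by a 10x10 square); ``mask_wide`` uses a 15x15
    square.  By construction ``mask_wide ⊆ mask_narrow ⊆ foreground``."""

    foreground: np.ndarray
    mask_narrow: np.ndarray
    mask_wide: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        for name in ("foreground", "mask_narrow", "mask_wide"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (self.foreground.shape == self.mask_narrow.shape == self.mask_wide.shape):
            raise FormatError("ROI masks must share one shape")

    @property
    def evaluation_roi(self) -> np.ndarray:
        """Intersection of the two masks — the region detection can mark."""
        return self.mask_narrow & self.mask_wide


@dataclass
class VeinDetection:
    """Binary vein mask in the SWIR grid plus the ROI it was computed under."""

    mask: np.ndarray
    method: str
    roi: RoiMasks
    per_mask: tuple | None = None  # (detection under mask_narrow, under mask_wide)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class SwirD:
    """Fused SWIR-D product: the SWIR image with a registered depth and 3-D
    coordinate per SWIR pixel.  ``valid`` is false where no TOF sample maps
    within the interpolation radius."""

    swir: SwirImage
    depth_reg: np.ndarray
    xyz_reg: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.swir.height, self.swir.width)
        self.depth_reg = np.asarray(self.depth_reg, dtype=float)
        self.xyz_reg = np.asarray(self.xyz_reg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depth_reg.shape != shape or self.valid.shape != shape:
            raise FormatError("SwirD rasters must match the SWIR grid")
        if self.xyz_reg.shape != shape + (3,):
            raise FormatError("xyz_reg must have shape (rows, cols, 3)")
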