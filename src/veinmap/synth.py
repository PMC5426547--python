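"""Seeded synthetic phantom scenes for end-to-end testing without cameras.

A phantom emulates the physics the pipeline relies on: an illuminated limb
is a bright capsule-shaped foreground on a dark table; subcutaneous veins are
smooth curvilinear structures whose NIR absorption darkens the reflectance
with a Gaussian cross-sectional dent; illumination is non-uniform
(multiplicative ramp) and the sensor adds Gaussian read noise.  The same
scene is viewed by a low-resolution time-of-flight camera with radial lens
distortion, related to the SWIR grid by a planted 2-D linear map, over a
smooth surface (plane or Gaussian bump) at working distance.

Everything is deterministic for a fixed seed; changing only the seed changes
the noise and vein-path realizations but not the summary geometry (vein
count, surface model, grid sizes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import geometry
from .io import make_tof_frame
from .types import (
    CameraIntrinsics,
    ControlPointPairs,
    DegenerateInputError,
    LinearMap2D,
    SwirImage,
    TofFrame,
)

__all__ = ["PhantomSpec", "SceneBundle", "generate_phantom", "generate_tof_scene", "generate_scene"]


def _default_tof_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=250.0, fy=250.0, cx=87.5, cy=71.5,
                            k1=-0.2, k2=0.05, k3=0.0)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scene.

    Intensity levels and noise are fractions of the full SWIR scale; sizes
    are pixels; depths are millimetres.  Grid sizes default to the nominal
    camera resolutions (SWIR 636x508 at 14 bit, TOF 176x144) so the ~3.6x
    resolution ratio the registration must bridge is exercised.
    """

    swir_shape: tuple[int, int] = (508, 636)   # (rows, cols)
    bit_depth: int = 14
    background_level: float = 0.04
    foreground_level: float = 0.55
    illumination_gradient: float = 0.08        # multiplicative ramp amplitude
    arm_radius_frac: float = 0.30              # capsule radius / image height

    vein_count: int = 3
    vein_width: float = 5.0                    # full width of the truth band, px
    vein_wiggle: float = 30.0                  # control-path curvature amplitude, px
    vein_darkening: float = 0.30               # fractional dent depth in (0, 1)
    noise_sigma: float = 0.01                  # additive Gaussian, fraction of full scale

    tof_shape: tuple[int, int] = (144, 176)    # (rows, cols)
    tof_intrinsics: CameraIntrinsics = field(default_factory=_default_tof_intrinsics)
    surface: str = "plane"                     # "plane" or "bump"
    surface_z0: float = 400.0                  # working distance, mm
    bump_amplitude: float = 25.0               # mm, toward the camera
    bump_sigma: float = 60.0                   # mm

    map_rotation_deg: float = 2.0              # planted map rotation
    pair_count: int = 100
    pair_jitter: float = 0.0                   # SWIR px, Gaussian, on inlier pairs
    outlier_fraction: float = 0.0
    outlier_epsilon: float = 2.0               # outliers violate the map by > this

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vein_darkening < 1.0:
            raise DegenerateInputError("vein darkening must be in [0, 1)")
        if self.vein_width < 2:
            raise DegenerateInputError("vein width must be at least 2 px")
        if self.surface not in ("plane", "bump"):
            raise DegenerateInputError(f"unknown surface model {self.surface!r}")
        arm_diameter = 2 * self.arm_radius_frac * self.swir_shape[0]
        if self.vein_width >= arm_diameter:
            raise DegenerateInputError("vein width exceeds the foreground extent")

    # ---- planted geometry -------------------------------------------------

    def planted_map(self) -> LinearMap2D:
        """TOF (undistorted) pixel → SWIR pixel map: per-axis scale bridging
        the two grids, a small rotation, and a center-aligning translation."""
        th = np.deg2rad(self.map_rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        scale = np.diag([
            self.swir_shape[1] / self.tof_shape[1],
            self.swir_shape[0] / self.tof_shape[0],
        ])
        R = scale @ rot
        c_tof = np.array([(self.tof_shape[1] - 1) / 2, (self.tof_shape[0] - 1) / 2])
        c_swir = np.array([(self.swir_shape[1] - 1) / 2, (self.swir_shape[0] - 1) / 2])
        T = c_swir - R @ c_tof
        return LinearMap2D(R=R, T=T)

    def surface_height(self, x_mm, y_mm):
        """Surface z (mm) at lateral camera-frame coordinates (x, y) in mm."""
        if self.surface == "plane":
            return np.broadcast_to(
                np.asarray(self.surface_z0, dtype=float), np.shape(x_mm)
            ).copy() if np.shape(x_mm) else float(self.surface_z0)
        r2 = np.asarray(x_mm, dtype=float) ** 2 + np.asarray(y_mm, dtype=float) ** 2
        return self.surface_z0 - self.bump_amplitude * np.exp(
            -r2 / (2.0 * self.bump_sigma**2)
        )

    # ---- (de)serialization ------------------------------------------------

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["tof_intrinsics"] = CameraIntrinsics.from_dict(d["tof_intrinsics"])
        d["swir_shape"] = tuple(d["swir_shape"])
        d["tof_shape"] = tuple(d["tof_shape"])
        return cls(**d)


def _capsule_mask(shape: tuple[int, int], radius_frac: float) -> np.ndarray:
    """Arm-shaped foreground: all pixels within ``radius`` of a horizontal
    central segment."""
    H, W = shape
    radius = radius_frac * H
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    x0, x1 = 0.12 * W, 0.88 * W
    xc = np.clip(xx, x0, x1)
    return (xx - xc) ** 2 + (yy - H / 2) ** 2 <= radius**2


def _vein_centerlines(
    spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Boolean canvas with the planted centerline pixels of every vein."""
    H, W = spec.swir_shape
    radius = spec.arm_radius_frac * H
    canvas = np.zeros((H, W), dtype=bool)
    x0, x1 = 0.14 * W, 0.86 * W
    # evenly spread base offsets inside the capsule, jittered per seed
    base = np.linspace(-0.45, 0.45, spec.vein_count) * radius if spec.vein_count > 1 \
        else np.zeros(1)
    for i in range(spec.vein_count):
        off = base[i] + rng.uniform(-0.08, 0.08) * radius
        amp = rng.uniform(0.4, 1.0) * spec.vein_wiggle
        freq = rng.uniform(1.0, 2.5)
        phase = rng.uniform(0.0, 2 * np.pi)
        n = int(4 * (x1 - x0))
        t = np.linspace(0.0, 1.0, n)
        xs = x0 + t * (x1 - x0)
        ys = H / 2 + off + amp * np.sin(freq * np.pi * t + phase)
        limit = radius - spec.vein_width
        ys = np.clip(ys, H / 2 - limit, H / 2 + limit)
        r = np.rint(ys).astype(int)
        c = np.rint(xs).astype(int)
        ok = (r >= 0) & (r < H) & (c >= 0) & (c < W)
        canvas[r[ok], c[ok]] = True
    return canvas


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[SwirImage, np.ndarray, np.ndarray]:
    """Render one SWIR phantom.

    Returns ``(image, truth_vein_mask, foreground_mask)``.  The truth mask
    marks pixels within half a vein width of any planted centerline.
    """
    rng = np.random.default_rng([spec.seed, 0])
    H, W = spec.swir_shape
    maxv = float((1 << spec.bit_depth) - 1)
    fg = _capsule_mask((H, W), spec.arm_radius_frac)
    img = np.where(fg, spec.foreground_level, spec.background_level) * maxv

    centers = _vein_centerlines(spec, rng)
    if centers.any():
        dist = ndimage.distance_transform_edt(~centers)
    else:
        dist = np.full((H, W), np.inf)
    half = spec.vein_width / 2.0
    truth = (dist <= half) & fg
    # Gaussian cross-section with sigma = width/4: the absorption dip is
    # essentially contained within the declared vein width (±2 sigma)
    dent = 1.0 - spec.vein_darkening * np.exp(-(dist**2) / (2.0 * (half / 2.0) ** 2))
    img = np.where(fg, img * dent, img)

    if spec.illumination_gradient > 0:
        psi = rng.uniform(0.0, 2 * np.pi)
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        proj = (xx - W / 2) * np.cos(psi) + (yy - H / 2) * np.sin(psi)
        proj /= np.abs(proj).max()
        img = img * (1.0 + spec.illumination_gradient * proj)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma * maxv, size=img.shape)

    pixels = np.clip(np.rint(img), 0, maxv).astype(np.uint16)
    return SwirImage(pixels=pixels, bit_depth=spec.bit_depth), truth, fg


def _render_depth(spec: PhantomSpec) -> np.ndarray:
    """Depth raster at TOF resolution, with the radial distortion of the
    sampling grid applied (pixels observe along distorted rays)."""
    H, W = spec.tof_shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    obs = np.stack([cols, rows], axis=-1)
    ray = geometry.undistort_point(
        geometry.normalize_pixel(obs, spec.tof_intrinsics), spec.tof_intrinsics
    )
    if spec.surface == "plane":
        return np.full((H, W), spec.surface_z0, dtype=float)
    z = np.full((H, W), spec.surface_z0, dtype=float)
    for _ in range(40):  # fixed point: z = f(x_n z, y_n z); gentle bump → contraction
        z_new = spec.surface_height(ray[..., 0] * z, ray[..., 1] * z)
        if np.abs(z_new - z).max() < 1e-9:
            z = z_new
            break
        z = z_new
    return z


def generate_tof_scene(
    spec: PhantomSpec, swir: SwirImage | None = None
) -> tuple[TofFrame, ControlPointPairs, LinearMap2D]:
    """Render the TOF view of the phantom plus registration ground truth.

    Returns ``(frame, pairs, planted_map)``.  Control-point pairs store the
    observed (distorted) TOF pixel coordinate as F1 and the SWIR pixel
    coordinate as F2; inlier pairs satisfy ``map(undistort(F1)) == F2``
    exactly (up to the optional jitter), and exactly ``ceil(outlier_fraction
    * pair_count)`` pairs violate the map by more than ``outlier_epsilon``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    m = spec.planted_map()
    intr = spec.tof_intrinsics
    depth = _render_depth(spec)

    if swir is None:
        swir, _, _ = generate_phantom(spec)
    # amplitude: the SWIR reflectance as seen through the planted map
    H, W = spec.tof_shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    obs = np.stack([cols, rows], axis=-1)
    ideal = geometry.undistort_pixel(obs.reshape(-1, 2), intr)
    mapped = m.apply(ideal).reshape(H, W, 2)
    amplitude = ndimage.map_coordinates(
        swir.pixels.astype(float),
        [mapped[..., 1], mapped[..., 0]],
        order=1, mode="constant", cval=0.0,
    ) / 16.0
    frame = make_tof_frame(depth, amplitude, intr)

    # control points on the foreground (mapped position inside the SWIR grid)
    sh, sw = spec.swir_shape
    n = spec.pair_count
    u = np.empty((n, 2))
    got = 0
    while got < n:
        cand = np.stack(
            [rng.uniform(3, W - 4, size=n), rng.uniform(3, H - 4, size=n)], axis=1
        )
        proj = m.apply(cand)
        ok = (
            (proj[:, 0] > 10) & (proj[:, 0] < sw - 11)
            & (proj[:, 1] > 10) & (proj[:, 1] < sh - 11)
        )
        take = min(int(ok.sum()), n - got)
        u[got : got + take] = cand[ok][:take]
        got += take
    x1 = geometry.distort_pixel(u, intr)
    x2 = m.apply(u)
    if spec.pair_jitter > 0:
        x2 = x2 + rng.normal(0.0, spec.pair_jitter, size=x2.shape)

    n_out = int(np.ceil(spec.outlier_fraction * n))
    if n_out > 0:
        idx = rng.choice(n, size=n_out, replace=False)
        for i in idx:
            while True:
                cand = np.array([rng.uniform(0, sw - 1), rng.uniform(0, sh - 1)])
                if np.linalg.norm(cand - m.apply(u[i])) > 3.0 * spec.outlier_epsilon:
                    x2[i] = cand
                    break
    return frame, ControlPointPairs(x1, x2), m


@dataclass
class SceneBundle:
    """One fully rendered scene with all ground truth."""

    spec: PhantomSpec
    swir: SwirImage
    truth: np.ndarray
    foreground: np.ndarray
    tof: TofFrame
    pairs: ControlPointPairs
    planted_map: LinearMap2D


def generate_scene(spec: PhantomSpec) -> SceneBundle:
    """Render the SWIR phantom and its TOF view in one call."""
    swir, truth, fg = generate_phantom(spec)
    tof, pairs, m = generate_tof_scene(spec, swir=swir)
    return SceneBundle(
        spec=spec, swir=swir, truth=truth, foreground=fg,
        tof=tof, pairs=pairs, planted_map=m,
    )
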