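"""Radial distortion, TOF→SWIR registration and 3-D vein mapping.

The range camera and the SWIR camera are rigidly mounted with parallel image
planes, so a single offline-estimated 2-D linear map ``p_swir = R p_tof + T``
(R a general 2x2 matrix, T a 2-vector) relates undistorted TOF pixel
coordinates to SWIR pixel coordinates.  The map is estimated once by RANSAC
over manually (or synthetically) matched control points and then applied
online to every frame.

Distortion handling follows the Brown radial model

    x_d = x (1 + k1 r^2 + k2 r^4 + k3 r^6),   r^2 = x^2 + y^2

on dimensionless normalized coordinates; the inverse is computed by damped
fixed-point iteration.  Only the TOF side is corrected — the SWIR image is
assumed rectified upstream.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import (
    CameraIntrinsics,
    ControlPointPairs,
    DegenerateInputError,
    LinearMap2D,
    RegistrationError,
    SwirD,
    SwirImage,
    TofFrame,
    VeinDetection,
)

__all__ = [
    "normalize_pixel",
    "denormalize_pixel",
    "distort_point",
    "undistort_point",
    "undistort_pixel",
    "distort_pixel",
    "estimate_linear_map",
    "count_inliers",
    "ransac_register",
    "register_tof_to_swir",
    "map_veins_3d",
]


def normalize_pixel(p: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Pixel ``(x=col, y=row)`` → dimensionless normalized image coordinates:
    translate to the optical center and divide by the focal length."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    out[..., 0] = (p[..., 0] - intr.cx) / intr.fx
    out[..., 1] = (p[..., 1] - intr.cy) / intr.fy
    return out


def denormalize_pixel(p: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Inverse of :func:`normalize_pixel`."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    out[..., 0] = p[..., 0] * intr.fx + intr.cx
    out[..., 1] = p[..., 1] * intr.fy + intr.cy
    return out


def _radial_factor(p: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    r2 = p[..., 0] ** 2 + p[..., 1] ** 2
    return 1.0 + intr.k1 * r2 + intr.k2 * r2**2 + intr.k3 * r2**3


def distort_point(p: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Apply the radial model to normalized coordinates (forward direction:
    ideal → observed)."""
    p = np.asarray(p, dtype=float)
    return p * _radial_factor(p, intr)[..., None]


def undistort_point(
    p_d: np.ndarray,
    intr: CameraIntrinsics,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert the radial model by fixed-point iteration x ← x_d / f(r(x)).

    Raises
    ------
    RegistrationError
        If the iteration has not contracted below ``tol`` after ``max_iter``
        steps (coefficients too strong / point outside the invertible zone).
    """
    p_d = np.asarray(p_d, dtype=float)
    x = p_d.copy()
    for _ in range(max_iter):
        x_new = p_d / _radial_factor(x, intr)[..., None]
        step = np.abs(x_new - x).max() if x.size else 0.0
        x = x_new
        if step < tol:
            return x
    raise RegistrationError(
        f"distortion inversion did not converge in {max_iter} iterations"
    )


def undistort_pixel(p: np.ndarray, intr: CameraIntrinsics, **kw) -> np.ndarray:
    """Observed (distorted) pixel coordinates → ideal pixel coordinates."""
    return denormalize_pixel(undistort_point(normalize_pixel(p, intr), intr, **kw), intr)


def distort_pixel(p: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Ideal pixel coordinates → observed (distorted) pixel coordinates."""
    return denormalize_pixel(distort_point(normalize_pixel(p, intr), intr), intr)


def _fit_lstsq(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares (R, T) for R @ x1_i + T ≈ x2_i over all pairs."""
    n = x1.shape[0]
    A = np.hstack([x1, np.ones((n, 1))])  # (n, 3); params per output coord
    if np.linalg.matrix_rank(A) < 3:
        raise DegenerateInputError(
            "control points are collinear or duplicated; cannot fit a 2-D linear map"
        )
    sol, *_ = np.linalg.lstsq(A, x2, rcond=None)  # (3, 2)
    R = sol[:2, :].T
    T = sol[2, :]
    return R, T


def estimate_linear_map(pairs: ControlPointPairs) -> LinearMap2D:
    """Least-squares estimate of the 2x2 + translation map over *all* pairs.

    Requires at least 3 non-collinear points in the TOF frame."""
    if len(pairs) < 3:
        raise DegenerateInputError("need at least 3 control point pairs")
    R, T = _fit_lstsq(pairs.x1, pairs.x2)
    return LinearMap2D(R=R, T=T, inliers=len(pairs))


def residuals(pairs: ControlPointPairs, m: LinearMap2D) -> np.ndarray:
    """Euclidean reprojection error per pair, in SWIR pixels."""
    return np.linalg.norm(m.apply(pairs.x1) - pairs.x2, axis=1)


def count_inliers(
    pairs: ControlPointPairs, m: LinearMap2D, epsilon: float | None = None
) -> int:
    """Consensus count f0 = #{i : ||R x1_i + T − x2_i|| < ε} (strict)."""
    eps = m.epsilon if epsilon is None else epsilon
    if eps is None:
        raise ValueError("epsilon must be given on the map or as an argument")
    return int((residuals(pairs, m) < eps).sum())


def ransac_register(
    pairs: ControlPointPairs,
    epsilon: float = 2.0,
    iterations: int = 2000,
    seed: int = 0,
) -> LinearMap2D:
    """RANSAC estimate of the TOF→SWIR linear map.

    Repeatedly fits minimal 3-pair samples, scores each candidate by its
    inlier count f0 under threshold ``epsilon`` (strict Euclidean test), keeps
    the candidate with the largest f0 (first found wins ties) and refits by
    least squares on its inlier set.  Fully deterministic for a fixed seed.
    """
    n = len(pairs)
    if n < 3:
        raise DegenerateInputError("need at least 3 control point pairs")
    rng = np.random.default_rng(seed)
    best_f0 = -1
    best_inliers: np.ndarray | None = None
    for _ in range(iterations):
        idx = rng.choice(n, size=3, replace=False)
        try:
            R, T = _fit_lstsq(pairs.x1[idx], pairs.x2[idx])
            cand = LinearMap2D(R=R, T=T)
        except DegenerateInputError:
            continue
        e = residuals(pairs, cand)
        f0 = int((e < epsilon).sum())
        if f0 > best_f0:
            best_f0 = f0
            best_inliers = e < epsilon
    if best_inliers is None or best_f0 < 3:
        raise RegistrationError("RANSAC found no candidate with at least 3 inliers")
    R, T = _fit_lstsq(pairs.x1[best_inliers], pairs.x2[best_inliers])
    final = LinearMap2D(R=R, T=T, epsilon=epsilon, seed=seed)
    final.inliers = count_inliers(pairs, final, epsilon)
    return final


def register_tof_to_swir(
    tof: TofFrame,
    m: LinearMap2D,
    tof_intr: CameraIntrinsics,
    swir: SwirImage,
    fill_radius: float = 4.0,
) -> SwirD:
    """Resample the TOF range data into the SWIR pixel grid (SWIR-D fusion).

    Every valid TOF pixel is undistorted, mapped by (R, T) into the SWIR
    grid and splatted onto the nearest pixel; the remaining gaps (the TOF
    grid is ~3.6x coarser) are filled from the nearest splatted sample up to
    ``fill_radius`` SWIR pixels.  Pixels farther than that stay invalid.
    """
    H, W = swir.height, swir.width
    depth_reg = np.zeros((H, W), dtype=float)
    xyz_reg = np.zeros((H, W, 3), dtype=float)
    valid = np.zeros((H, W), dtype=bool)

    vr, vc = np.nonzero(tof.valid)
    if vr.size:
        obs = np.stack([vc.astype(float), vr.astype(float)], axis=1)  # (x, y)
        ideal = undistort_pixel(obs, tof_intr)
        mapped = m.apply(ideal)
        tx = np.rint(mapped[:, 0]).astype(int)
        ty = np.rint(mapped[:, 1]).astype(int)
        inside = (tx >= 0) & (tx < W) & (ty >= 0) & (ty < H)
        # nearest sample wins a contested pixel: write in decreasing order of
        # distance from the mapped position to the pixel center
        d2 = (mapped[:, 0] - tx) ** 2 + (mapped[:, 1] - ty) ** 2
        order = np.argsort(-d2[inside])
        tx, ty = tx[inside][order], ty[inside][order]
        src_r, src_c = vr[inside][order], vc[inside][order]
        depth_reg[ty, tx] = tof.depth[src_r, src_c]
        xyz_reg[ty, tx] = tof.xyz[src_r, src_c]
        valid[ty, tx] = True

    if valid.any() and not valid.all() and fill_radius > 0:
        dist, (ir, ic) = ndimage.distance_transform_edt(~valid, return_indices=True)
        fill = (~valid) & (dist <= fill_radius)
        depth_reg[fill] = depth_reg[ir[fill], ic[fill]]
        xyz_reg[fill] = xyz_reg[ir[fill], ic[fill]]
        valid |= fill

    return SwirD(swir=swir, depth_reg=depth_reg, xyz_reg=xyz_reg, valid=valid)


def map_veins_3d(det: VeinDetection, fused: SwirD) -> np.ndarray:
    """3-D point per detected vein pixel with a valid registered depth.

    Returns an ``(M, 3)`` array of millimetre coordinates in the TOF camera
    frame, one row per pixel of ``det.mask & fused.valid``."""
    if det.mask.shape != fused.valid.shape:
        raise ValueError("detection mask and fused frame shapes differ")
    sel = det.mask & fused.valid
    return fused.xyz_reg[sel].reshape(-1, 3)
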