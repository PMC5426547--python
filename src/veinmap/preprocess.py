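"""Foreground segmentation, edge-discarding ROI masks and contrast enhancement.

The illuminated limb reflects the 940 nm source strongly, so the foreground
is the bright side of a global Otsu split of the raw SWIR image.  The
transition band between background and foreground produces spurious ridges in
the extractors, so the background is dilated twice — with 10 px and 15 px
square structuring elements — giving two nested ROI masks; detection is run
under each and the results are AND-ed downstream.

Contrast enhancement is CLAHE followed by a linear intensity adjustment that
saturates 1% of the masked pixels at each end of the output range.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure

from .types import DegenerateInputError, RoiMasks, SwirImage

__all__ = [
    "otsu_threshold",
    "segment_foreground",
    "build_masks",
    "enhance",
]

DEFAULT_MASK_WIDTHS = (10, 15)


def otsu_threshold(img: SwirImage | np.ndarray, bins: int | None = None) -> int:
    """Global threshold minimizing the weighted intra-class intensity variance.

    Candidate levels are every integer intensity ``t``; pixels with value
    ``> t`` form the foreground class.  Among minimizing levels the lowest is
    returned.  A constant image has no two classes to separate and raises
    :class:`DegenerateInputError`.

    Parameters
    ----------
    img : SwirImage or integer ndarray
    bins : int, optional
        Number of histogram levels; defaults to the full intensity range
        (``2**bit_depth`` for a :class:`SwirImage`).
    """
    if isinstance(img, SwirImage):
        data = img.pixels
        nlev = bins if bins is not None else (1 << img.bit_depth)
    else:
        data = np.asarray(img)
        nlev = bins if bins is not None else int(data.max()) + 1
    flat = data.reshape(-1).astype(np.int64)
    if flat.min() == flat.max():
        raise DegenerateInputError("constant image: histogram is degenerate")
    hist = np.bincount(flat, minlength=nlev).astype(float)
    n = hist.sum()
    levels = np.arange(nlev, dtype=float)

    # cumulative moments: class 0 = values <= t, class 1 = values > t
    w0 = np.cumsum(hist)
    s0 = np.cumsum(hist * levels)
    q0 = np.cumsum(hist * levels**2)
    w1 = n - w0
    s1 = s0[-1] - s0
    q1 = q0[-1] - q0

    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = q0 / w0 - (s0 / w0) ** 2
        var1 = q1 / w1 - (s1 / w1) ** 2
    var0 = np.where(w0 > 0, var0, 0.0)
    var1 = np.where(w1 > 0, var1, 0.0)
    within = (w0 * var0 + w1 * var1) / n

    valid = (w0 > 0) & (w1 > 0)  # both classes non-empty
    within[~valid] = np.inf
    return int(np.argmin(within))


def segment_foreground(
    img: SwirImage,
    invert: bool = False,
    largest_component: bool = True,
    bins: int | None = None,
) -> tuple[np.ndarray, int]:
    """Binarize with Otsu's threshold and return ``(foreground, level)``.

    Foreground is the bright class (``pixels > level``) unless ``invert``;
    with ``largest_component`` only the largest connected component is kept,
    dropping bright speckle away from the limb.
    """
    level = otsu_threshold(img, bins=bins)
    fg = img.pixels <= level if invert else img.pixels > level
    if largest_component and fg.any():
        lab, nlab = ndimage.label(fg)
        if nlab > 1:
            sizes = np.bincount(lab.reshape(-1))
            sizes[0] = 0
            fg = lab == int(np.argmax(sizes))
    return fg, level


def _erode_square(mask: np.ndarray, width: int) -> np.ndarray:
    """Erosion by a width x width square anchored at element index
    (width//2, width//2) — i.e. for even widths the element extends one pixel
    farther toward the top-left.  Equivalent to complementing a dilation of
    the background by the same element."""
    if width <= 1:
        return mask.copy()
    structure = np.ones((width, width), dtype=bool)
    # scipy centers a size-w footprint at w//2 already; origin=0 keeps that.
    return ndimage.binary_erosion(mask, structure=structure, border_value=True)


def build_masks(
    foreground: np.ndarray,
    widths: tuple[int, int] = DEFAULT_MASK_WIDTHS,
    threshold: float = 0,
) -> RoiMasks:
    """Build the two edge-discarding ROI masks from the foreground raster.

    For each width ``w`` the background region is dilated by a ``w x w``
    square structuring element and the mask is the complement — equivalently
    the foreground eroded by that element.  Border pixels are treated as
    foreground so that an all-foreground raster yields all-true masks.
    """
    foreground = np.asarray(foreground, dtype=bool)
    w_narrow, w_wide = sorted(widths)
    return RoiMasks(
        foreground=foreground,
        mask_narrow=_erode_square(foreground, w_narrow),
        mask_wide=_erode_square(foreground, w_wide),
        threshold=threshold,
    )


def enhance(
    img: SwirImage,
    mask: np.ndarray,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
    saturation: float = 0.01,
) -> np.ndarray:
    """CLAHE within the masked region, then a linear intensity adjustment.

    The image is equalized tile-wise with a clipped histogram (background
    pixels are filled with the masked mean first so edge tiles are not skewed
    by the dark table), after which intensities are remapped linearly so that
    the ``saturation`` and ``1 - saturation`` quantiles of the masked pixels
    land on the extremes of ``[0, 2**bit_depth - 1]``; values beyond saturate.
    The remap is monotone, so intensity ordering within a tile is preserved.

    Returns a float array on the input intensity scale, zeroed outside the
    mask.  A constant masked region passes through unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask: nothing to enhance")
    maxv = float(img.max_value)
    work = img.pixels.astype(float) / maxv
    masked_vals = work[mask]
    out = np.zeros_like(work)
    if masked_vals.min() == masked_vals.max():
        out[mask] = masked_vals * maxv  # no contrast to equalize
        return out
    work = np.where(mask, work, masked_vals.mean())
    kernel = (
        max(1, img.height // tiles[0]),
        max(1, img.width // tiles[1]),
    )
    eq = exposure.equalize_adapthist(work, kernel_size=kernel, clip_limit=clip_limit)
    lo, hi = np.quantile(eq[mask], [saturation, 1.0 - saturation])
    if hi <= lo:
        out[mask] = eq[mask] * maxv
        return out
    stretched = np.clip((eq - lo) / (hi - lo), 0.0, 1.0)
    out[mask] = stretched[mask] * maxv
    return out
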