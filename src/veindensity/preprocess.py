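"""Raw micrograph -> veins-as-foreground binary mask.

Stage chain: greyscale conversion, contrast-limited adaptive histogram
equalization (CLAHE), mean blur, Otsu binarization, complement. On a
starch-stained micrograph veins are dark on a light background, so after
thresholding they fall in class 0; the complement step re-orients the mask
so that veins are foreground (value 1).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import uniform_filter
from skimage import exposure

logger = logging.getLogger("veindensity")

__all__ = [
    "to_greyscale",
    "enhance_contrast",
    "mean_blur",
    "otsu_threshold",
    "binarize",
    "orient_foreground",
    "preprocess_image",
]

#: ITU-R BT.601 luminance weights, the conventional RGB->grey projection,
#: normalized to sum exactly to 1 so achromatic input is preserved.
LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])
LUMA_WEIGHTS = LUMA_WEIGHTS / LUMA_WEIGHTS.sum()


def to_greyscale(raster: np.ndarray) -> np.ndarray:
    """Collapse an RGB raster to luminance; pass greyscale through.

    Output intensities lie in [0, 1]; greyscale input outside that range is
    min-max rescaled.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if raster.ndim == 3:
        if raster.shape[2] != 3:
            raise ValueError(f"expected 1 or 3 channels, got {raster.shape[2]}")
        grey = raster @ LUMA_WEIGHTS
    elif raster.ndim == 2:
        grey = raster
    else:
        raise ValueError(f"expected a 2-D or 3-D raster, got ndim={raster.ndim}")
    lo, hi = grey.min(), grey.max()
    if lo < 0.0 or hi > 1.0:
        grey = np.zeros_like(grey) if hi == lo else (grey - lo) / (hi - lo)
    return np.clip(grey, 0.0, 1.0)


def enhance_contrast(img: np.ndarray, clip_limit: float = 0.01,
                     tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """CLAHE over a (rows, cols) tile grid; output in [0, 1].

    A constant image is returned unchanged (there is no contrast to
    enhance, and histogram equalization of a single level is degenerate).
    If the image is smaller than a single tile the method falls back to
    global histogram equalization with a warning.
    """
    img = np.asarray(img, dtype=np.float64)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    rows, cols = tile_grid
    if np.ptp(img) == 0.0:
        return img.copy()
    tile_h, tile_w = img.shape[0] // rows, img.shape[1] // cols
    if tile_h < 1 or tile_w < 1:
        logger.warning(
            "image %s smaller than one %dx%d CLAHE tile; using global equalization",
            img.shape, rows, cols)
        return exposure.equalize_hist(img)
    return exposure.equalize_adapthist(img, kernel_size=(tile_h, tile_w), clip_limit=clip_limit)


def mean_blur(img: np.ndarray, w: int = 20) -> np.ndarray:
    """Replace each pixel by the mean of its (2w+1) x (2w+1) window.

    Borders are handled by replicate padding, which avoids darkening the
    margins and thereby biasing the subsequent Otsu threshold.
    """
    img = np.asarray(img, dtype=np.float64)
    if w < 1:
        raise ValueError("w must be >= 1")
    if w >= min(img.shape):
        raise ValueError(f"w={w} too large for image of shape {img.shape}")
    return uniform_filter(img, size=2 * w + 1, mode="nearest")


def otsu_threshold(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over a fixed-range [0, 1] histogram.

    Maximizes the between-class variance over ``nbins`` equal-width bins on
    [0, 1] and returns the centre of the winning bin (first bin on ties).
    A constant image has zero between-class variance for every split; its
    own value is returned so that the strict ``>`` comparison yields an
    empty mask.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    if np.ptp(img) == 0.0:
        return float(img.flat[0])
    counts, edges = np.histogram(img, bins=nbins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = counts.astype(np.float64) / counts.sum()
    omega0 = np.cumsum(p)                      # class-0 weight for split after bin k
    mu = np.cumsum(p * centers)                # unnormalized class-0 mean
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu) ** 2 / (omega0 * (1.0 - omega0))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return float(centers[int(np.argmax(sigma_b))])


def binarize(img: np.ndarray, threshold_override: float | None = None) -> np.ndarray:
    """Threshold to {0, 1}: pixels strictly above the threshold become 1.

    The threshold is Otsu's unless ``threshold_override`` is given. A
    constant image yields an all-zero mask (callers flag it downstream).
    """
    img = np.asarray(img, dtype=np.float64)
    t = otsu_threshold(img) if threshold_override is None else float(threshold_override)
    return (img > t).astype(np.uint8)


def orient_foreground(mask: np.ndarray, invert_foreground: bool = True) -> np.ndarray:
    """Complement the mask when requested so veins end up as foreground (1)."""
    mask = np.asarray(mask).astype(np.uint8)
    return (1 - mask) if invert_foreground else mask.copy()


def preprocess_image(raster: np.ndarray, *, blur_w: int = 20,
                     clahe_clip_limit: float = 0.01,
                     clahe_tile_grid: tuple[int, int] = (8, 8),
                     threshold_override: float | None = None,
                     invert_foreground: bool = True) -> np.ndarray:
    """Run the full preprocessing chain on a raw raster.

    Returns the veins-as-foreground binary mask (uint8 in {0, 1}).
    """
    grey = to_greyscale(raster)
    enhanced = enhance_contrast(grey, clip_limit=clahe_clip_limit, tile_grid=clahe_tile_grid)
    blurred = mean_blur(enhanced, w=blur_w)
    mask = binarize(blurred, threshold_override=threshold_override)
    return orient_foreground(mask, invert_foreground)
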