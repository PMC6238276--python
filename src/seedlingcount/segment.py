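"""Seedling segmentation: excess green → Otsu → morphology.

Vegetation is separated from soil by the excess-green index computed on
chromatic (sum-normalized) channel coordinates, ``ExG = 1.8 g − r − b``,
thresholded by Otsu's between-class-variance criterion on a 256-bin
histogram, and cleaned by a morphological opening plus hole filling.
Chromatic coordinates make the index invariant to global brightness
scaling, so shaded and sunlit soil fall on the same side of the threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import DegenerateHistogramWarning
from .io import RunConfig, as_rgb_image


def excess_green(img: np.ndarray) -> np.ndarray:
    """Excess-green index on chromatic coordinates.

    Each pixel's channels are divided by their sum (pixels summing to zero
    get r = g = b = 1/3), then ExG = 1.8 g − r − b.  Values lie in
    [−1, 1.8].
    """
    img = as_rgb_image(img)
    total = img.sum(axis=-1)
    safe = np.where(total > 0, total, 1.0)
    r = np.where(total > 0, img[..., 0] / safe, 1.0 / 3.0)
    g = np.where(total > 0, img[..., 1] / safe, 1.0 / 3.0)
    b = np.where(total > 0, img[..., 2] / safe, 1.0 / 3.0)
    return 1.8 * g - r - b


def otsu_threshold(
    values: np.ndarray, nbins: int = 256
) -> tuple[float, np.ndarray]:
    """Otsu's threshold on a real-valued map.

    The value range is linearly divided into ``nbins`` bins; the returned
    threshold is the bin edge maximizing between-class variance, and the
    mask keeps values strictly above it.  A constant map triggers
    :class:`DegenerateHistogramWarning` and returns an all-false mask.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("map contains non-finite values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        warnings.warn(
            "degenerate histogram: constant map, returning empty mask",
            DegenerateHistogramWarning,
            stacklevel=2,
        )
        return vmin, np.zeros(values.shape, dtype=bool)

    hist, edges = np.histogram(values.ravel(), bins=nbins, range=(vmin, vmax))
    hist = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * centers)
    total, grand = w0[-1], m0[-1]
    # candidate split after bin t: class0 = bins <= t, class1 = bins > t
    w0c, w1c = w0[:-1], total - w0[:-1]
    valid = (w0c > 0) & (w1c > 0)
    between = np.zeros(nbins - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0[:-1] / w0c
        mu1 = (grand - m0[:-1]) / w1c
        between[valid] = (w0c * w1c * (mu0 - mu1) ** 2)[valid]
    t_star = int(np.argmax(between))
    threshold = float(edges[t_star + 1])
    return threshold, values > threshold


def morphological_cleanup(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Opening with a disk element, then filling of enclosed holes.

    Holes are background regions not 4-connected to the raster border.
    The composite is idempotent.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    opened = ndimage.binary_opening(
        np.asarray(mask, dtype=bool), structure=disk(radius)
    )
    return ndimage.binary_fill_holes(opened)


def segment_seedlings(img: np.ndarray, cfg: RunConfig | None = None) -> np.ndarray:
    """ExG → Otsu → morphological cleanup on a rectified target-area image."""
    cfg = cfg or RunConfig()
    exg = excess_green(img)
    _, raw = otsu_threshold(exg, nbins=cfg.otsu_bins)
    return morphological_cleanup(raw, radius=cfg.morph_radius)
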