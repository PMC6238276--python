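"""Characteristic values of a segmented stand: coverage and angular points.

Coverage degree ``Co`` is the foreground fraction of the target area.
Angular points ``Ha`` — leaf tips, leaf–leaf intersections and curl
folds — are local maxima of the Harris corner response
``R = det(M) − k·trace²(M)`` computed on the (smoothed) seedling mask.
Both rise and fall in opposite directions as leaves overlap or curl, which
is what makes their combination informative about the true plant count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError, UnknownVarietyError
from .io import RunConfig


@dataclass(frozen=True)
class HarrisParams:
    """Corner-detector parameters.

    ``k`` is the empirical Harris constant (0.04–0.06); ``window_sigma``
    sets the Gaussian window of the structure tensor; ``threshold_frac``
    and ``nms_radius`` turn the response map into a count (candidates above
    threshold_frac × max response, greedily thinned to a minimum pairwise
    distance of nms_radius pixels).
    """

    k: float = 0.04
    window_sigma: float = 1.5
    threshold_frac: float = 0.01
    nms_radius: int = 5

    def __post_init__(self) -> None:
        if not 0.04 <= self.k <= 0.06:
            raise InputError(f"k must lie in [0.04, 0.06], got {self.k}")
        if not 0.0 < self.threshold_frac < 1.0:
            raise InputError("threshold_frac must lie in (0, 1)")
        if self.nms_radius < 1:
            raise InputError("nms_radius must be >= 1")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "HarrisParams":
        return cls(
            k=cfg.harris_k,
            window_sigma=cfg.harris_window_sigma,
            threshold_frac=cfg.corner_threshold_frac,
            nms_radius=cfg.nms_radius,
        )


@dataclass(frozen=True)
class FeatureVector:
    """(Co, Ha, La, Va) — inputs of the counting models."""

    Co: float
    Ha: int
    La: float
    Va: float
    variety: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.Co <= 1.0:
            raise InputError(f"Co must lie in [0, 1], got {self.Co}")
        if self.Ha < 0 or int(self.Ha) != self.Ha:
            raise InputError(f"Ha must be a non-negative integer, got {self.Ha}")
        if not 1.0 <= self.La <= 3.0:
            raise InputError(f"La must lie in [1, 3], got {self.La}")
        if not self.Va > 0:
            raise InputError(f"Va must be positive, got {self.Va}")


def coverage_degree(mask: np.ndarray) -> float:
    """Foreground fraction of the mask (seedling area / image area)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise InputError("zero-size mask")
    return float(mask.sum()) / mask.size


def harris_response(mask: np.ndarray, p: HarrisParams | None = None) -> np.ndarray:
    """Harris corner response of a binary mask.

    The mask is lifted to floats and pre-smoothed with a Gaussian of scale
    ``window_sigma``; gradients are 3×3 Sobel derivatives; the structure
    tensor is windowed by the same Gaussian; the response is
    det(M) − k·trace²(M).
    """
    p = p or HarrisParams()
    f = ndimage.gaussian_filter(
        np.asarray(mask, dtype=float), sigma=p.window_sigma, mode="reflect"
    )
    ix = ndimage.sobel(f, axis=1, mode="reflect")
    iy = ndimage.sobel(f, axis=0, mode="reflect")
    w = dict(sigma=p.window_sigma, mode="reflect")
    ixx = ndimage.gaussian_filter(ix * ix, **w)
    iyy = ndimage.gaussian_filter(iy * iy, **w)
    ixy = ndimage.gaussian_filter(ix * iy, **w)
    det = ixx * iyy - ixy**2
    trace = ixx + iyy
    return det - p.k * trace**2


def count_angular_points(resp: np.ndarray, p: HarrisParams | None = None) -> int:
    """Number of suppressed local maxima of a Harris response map.

    Candidates are local maxima with response strictly above
    threshold_frac × max(resp) (zero if the map has no positive response);
    greedy non-maximum suppression, strongest first, keeps maxima at least
    ``nms_radius`` pixels apart.
    """
    p = p or HarrisParams()
    resp = np.asarray(resp, dtype=float)
    peak = resp.max() if resp.size else 0.0
    if peak <= 0:
        return 0
    threshold = p.threshold_frac * peak
    local_max = resp == ndimage.maximum_filter(resp, size=3, mode="reflect")
    rows, cols = np.nonzero((resp > threshold) & local_max)
    if len(rows) == 0:
        return 0
    strength = resp[rows, cols]
    order = np.lexsort((cols, rows, -strength))
    pts = np.column_stack([rows, cols]).astype(float)[order]

    kept = np.empty((0, 2))
    min_sq = float(p.nms_radius) ** 2
    for pt in pts:
        if kept.size == 0 or (((kept - pt) ** 2).sum(axis=1) >= min_sq).all():
            kept = np.vstack([kept, pt])
    return len(kept)


def extract_features(
    mask: np.ndarray,
    La: float,
    variety: str,
    cfg: RunConfig | None = None,
) -> FeatureVector:
    """Compute the full feature vector of a segmented target area."""
    cfg = cfg or RunConfig()
    if variety not in cfg.variety_table:
        known = ", ".join(sorted(cfg.variety_table))
        raise UnknownVarietyError(
            f"unknown variety {variety!r}; known varieties: {known}"
        )
    if not math.isfinite(La):
        raise InputError("leaf age must be finite")
    params = HarrisParams.from_config(cfg)
    co = coverage_degree(mask)
    ha = count_angular_points(harris_response(mask, params), params)
    return FeatureVector(
        Co=co, Ha=ha, La=float(La), Va=cfg.variety_table[variety], variety=variety
    )
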