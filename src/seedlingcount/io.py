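"""Image/table I/O, run configuration and result records.

Images are held as plain ``numpy`` arrays of shape ``(H, W, 3)`` with float
channels normalized to ``[0, 1]`` — the scale on which the white-frame
thresholds (channel sum > 2.1, r − b < 0.05) are meaningful.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InputError
from .models import DEFAULT_VARIETY_TABLE

logger = logging.getLogger("seedlingcount")

#: Keys a count record must carry before it is written to disk.
RESULT_FIELDS = ("Co", "Ha", "La", "Va", "SN", "model")

#: Required columns of an observation table (SN_true and site are optional).
TABLE_COLUMNS = ("image_id", "variety", "La", "Co", "Ha")


@dataclass
class RunConfig:
    """Tunable knobs of the counting pipeline.

    ``target_size`` is the side of the rectified square target area in
    pixels; 800 reproduces the working resolution of the method.  The Harris
    constant ``harris_k`` is restricted to its empirical 0.04–0.06 range.
    The frame thresholds (``frame_sum_min``, ``frame_rb_max``) are exposed
    because they were tuned to particular field scenes and may need
    adjustment for other cameras or lighting.
    """

    target_size: int = 800
    harris_k: float = 0.04
    harris_window_sigma: float = 1.5
    corner_threshold_frac: float = 0.01
    nms_radius: int = 5
    morph_radius: int = 1
    frame_sum_min: float = 2.1
    frame_rb_max: float = 0.05
    otsu_bins: int = 256
    variety_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIETY_TABLE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_size < 64:
            raise InputError(f"target_size must be >= 64, got {self.target_size}")
        if not 0.04 <= self.harris_k <= 0.06:
            raise InputError(
                f"harris_k must lie in [0.04, 0.06], got {self.harris_k}"
            )
        if not 0.0 < self.corner_threshold_frac < 1.0:
            raise InputError("corner_threshold_frac must lie in (0, 1)")
        if self.nms_radius < 1 or self.morph_radius < 1:
            raise InputError("nms_radius and morph_radius must be >= 1")


def as_rgb_image(arr: np.ndarray) -> np.ndarray:
    """Validate an array as an RGB image and return it as float64.

    Raises :class:`InputError` unless ``arr`` is H×W×3 with H, W ≥ 16 and
    all values in [0, 1].
    """
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"not RGB: expected H x W x 3 array, got shape {arr.shape}")
    if arr.shape[0] < 16 or arr.shape[1] < 16:
        raise InputError(f"image too small: {arr.shape[0]} x {arr.shape[1]} < 16 x 16")
    if not np.isfinite(arr).all():
        raise InputError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InputError("image channels must be normalized to [0, 1]")
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file into a [0, 1]-normalized H×W×3 float array.

    8-bit data is divided by 255, 16-bit by 65535; an alpha channel is
    discarded. Grayscale input is rejected ("not RGB").
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise InputError(f"file not found: {path}") from None
    except Exception as exc:  # undecodable content
        raise InputError(f"cannot decode image file {path}: {exc}") from exc
    if raw.ndim == 2:
        raise InputError(f"not RGB: {path} is a grayscale image")
    if raw.ndim != 3 or raw.shape[2] < 3:
        raise InputError(f"not RGB: {path} has shape {raw.shape}")
    raw = raw[:, :, :3]
    if raw.dtype == np.uint8:
        pixels = raw.astype(float) / 255.0
    elif raw.dtype == np.uint16:
        pixels = raw.astype(float) / 65535.0
    else:
        pixels = np.clip(raw.astype(float), 0.0, 1.0)
    return as_rgb_image(pixels)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image (or boolean mask) as an 8-bit PNG/JPEG."""
    arr = np.asarray(img)
    if arr.dtype == bool:
        data = (arr.astype(np.uint8)) * 255
    else:
        data = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def write_result(record: dict, path: str | Path) -> None:
    """Serialize a count record as JSON.

    The record must contain the fields Co, Ha, La, Va, SN and model, and all
    numeric fields must be finite.
    """
    missing = [k for k in RESULT_FIELDS if k not in record]
    if missing:
        raise InputError(f"missing fields in result record: {missing}")
    for key in ("Co", "Ha", "La", "Va", "SN"):
        value = record[key]
        if not isinstance(value, (int, float)) or not math.isfinite(value):
            raise InputError(f"non-finite feature in result record: {key}={value!r}")
    try:
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise InputError(f"cannot write result to {path}: {exc}") from exc


def read_result(path: str | Path) -> dict:
    """Read back a JSON count record written by :func:`write_result`."""
    with open(path) as fh:
        return json.load(fh)


def read_observation_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV of (image_id, variety, La, Co, Ha[, SN_true, site]) rows."""
    try:
        table = pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"file not found: {path}") from None
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"observation table {path} lacks columns {missing}")
    validate_observation_table(table)
    return table


def validate_observation_table(table: pd.DataFrame) -> None:
    """Check the value-range invariants of an observation table."""
    if ((table["Co"] < 0) | (table["Co"] > 1)).any():
        raise InputError("Co values must lie in [0, 1]")
    if (table["Ha"] < 0).any():
        raise InputError("Ha values must be non-negative")
    if "SN_true" in table.columns and (table["SN_true"] < 0).any():
        raise InputError("SN_true values must be non-negative")


def write_observation_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table as a headered CSV."""
    table.to_csv(path, index=False)
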