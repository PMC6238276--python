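"""Seedling-number estimation models.

Two model families map image features to the seedling number SN on a 1-m²
target area:

* **Stage models** — one linear equation per (variety, leaf stage):
  ``SN = coef_Ha * Ha + coef_Co * Co + intercept``.
* **Unified model** — a single equation across varieties and leaf ages:
  ``SN = Va * (a*Ha + b*Co + c) / (d*La)``, where Va is a per-variety
  multiplicative coefficient correcting for seedling habit (erect /
  half-erect / lax) and La is the mean leaf age of the stand.

The published coefficient sets ship as a versioned JSON data file and are
loaded by :func:`builtin_models`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, NamedTuple

from .errors import ClampWarning, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureVector

#: Published variety coefficients (Va): larger Va compensates smaller
#: per-plant coverage (erect habit), smaller Va compensates lax habit.
DEFAULT_VARIETY_TABLE = {"YM23": 1.05, "HM7": 0.86, "YF4": 1.12}


class SNEstimate(NamedTuple):
    """A seedling-number prediction with a clamp flag.

    ``clamped`` is True when the raw linear prediction was negative and the
    returned value was clipped to zero.
    """

    value: float
    clamped: bool


@dataclass(frozen=True)
class StageModel:
    """Per-variety, per-leaf-stage linear counting model."""

    coef_Ha: float
    coef_Co: float
    intercept: float
    variety: str | None = None
    stage: int | None = None

    def __post_init__(self) -> None:
        for name in ("coef_Ha", "coef_Co", "intercept"):
            if not math.isfinite(getattr(self, name)):
                raise InputError(f"non-finite coefficient {name}")
        if self.stage is not None and self.stage not in (1, 2, 3):
            raise InputError(f"stage must be 1, 2 or 3, got {self.stage}")


@dataclass(frozen=True)
class UnifiedModel:
    """Unified multi-variety, multi-stage counting model."""

    a: float
    b: float
    c: float
    d: float
    variety_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIETY_TABLE)
    )

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise InputError(f"d must be positive, got {self.d}")
        for name, va in self.variety_table.items():
            if not va > 0:
                raise InputError(f"Va for {name} must be positive, got {va}")


@dataclass(frozen=True)
class VarietyEntry:
    """Registry slot for one variety: Va plus its three stage models."""

    Va: float
    stages: dict[int, StageModel]

    def stage(self, s: int) -> StageModel:
        return self.stages[s]


@dataclass(frozen=True)
class ModelRegistry:
    """All built-in models: nine stage models and one unified model."""

    stage_models: tuple[StageModel, ...]
    unified: UnifiedModel

    def __getitem__(self, variety: str) -> VarietyEntry:
        if variety not in self.unified.variety_table:
            raise KeyError(variety)
        return VarietyEntry(
            Va=self.unified.variety_table[variety],
            stages={m.stage: m for m in self.stage_models if m.variety == variety},
        )

    def stage_model(self, variety: str, stage: int) -> StageModel:
        for m in self.stage_models:
            if m.variety == variety and m.stage == stage:
                return m
        raise KeyError((variety, stage))


def stage_from_leaf_age(la: float) -> int:
    """Nearest integer leaf stage for a (possibly non-integer) leaf age."""
    return int(min(3, max(1, math.floor(la + 0.5))))


def _clamp(raw: float) -> SNEstimate:
    if raw < 0.0:
        warnings.warn(
            f"negative seedling-number prediction {raw:.3f} clamped to 0",
            ClampWarning,
            stacklevel=3,
        )
        return SNEstimate(0.0, True)
    return SNEstimate(raw, False)


def predict_stagewise(f: "FeatureVector", m: StageModel) -> SNEstimate:
    """Evaluate a stage model on a feature vector.

    Raises :class:`InputError` when the feature vector's variety or leaf age
    does not match the model's variety/stage.
    """
    if not (math.isfinite(f.Co) and math.isfinite(f.Ha)):
        raise InputError("non-finite features")
    if m.variety is not None and f.variety is not None and f.variety != m.variety:
        raise InputError(f"variety mismatch: features {f.variety}, model {m.variety}")
    if m.stage is not None and stage_from_leaf_age(f.La) != m.stage:
        raise InputError(
            f"stage mismatch: leaf age {f.La} is stage {stage_from_leaf_age(f.La)}, "
            f"model is stage {m.stage}"
        )
    return _clamp(m.coef_Ha * f.Ha + m.coef_Co * f.Co + m.intercept)


def predict_unified(f: "FeatureVector", m: UnifiedModel) -> SNEstimate:
    """Evaluate the unified model SN = Va (a Ha + b Co + c) / (d La)."""
    if f.La <= 0:
        raise InputError(f"invalid leaf age: {f.La}")
    raw = f.Va * (m.a * f.Ha + m.b * f.Co + m.c) / (m.d * f.La)
    return _clamp(raw)


def builtin_models() -> ModelRegistry:
    """Load the published coefficient sets shipped with the package."""
    payload = json.loads(
        resources.files("seedlingcount.data")
        .joinpath("builtin_models.json")
        .read_text()
    )
    stage_models = tuple(StageModel(**row) for row in payload["stage_models"])
    unified = UnifiedModel(**payload["unified_model"])
    return ModelRegistry(stage_models=stage_models, unified=unified)
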