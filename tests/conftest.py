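"""Shared fixtures: desk-scale scene specs and run configuration.

Unit tests render scenes at a reduced scale (480-px canvas, 356-px inner
frame square standing for 1 m²) so the whole suite stays fast; the
end-to-end acceptance test uses the generator's full-scale defaults.
"""

import numpy as np
import pytest

from seedlingcount import RunConfig, SceneSpec

SMALL_SCENE = dict(
    canvas_size=480,
    frame_margin=48,
    frame_band=14,
    leaf_length_px=(32.0, 6.0),
    leaf_width_px=(4.5, 0.8),
)


@pytest.fixture
def small_spec():
    """Factory for reduced-scale scene specs."""

    def make(**kwargs) -> SceneSpec:
        return SceneSpec(**{**SMALL_SCENE, **kwargs})

    return make


@pytest.fixture
def small_cfg() -> RunConfig:
    """Run configuration matched to the reduced scene scale."""
    return RunConfig(target_size=356)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
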