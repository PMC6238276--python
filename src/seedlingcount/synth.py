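"""Synthetic field scenes with ground truth.

Generates photographs of a wheat seedling stand as the counting pipeline
expects them: a brown soil background with pale straw distractors, a white
square frame marking the 1-m² counting area, and green tapered leaf ribbons
(one to three per plant, optionally curled), the whole scene warped by a
bounded random perspective.  Every scene carries its ground truth — plant
count, leaf mask, frame corners and the exact homography — so each pipeline
stage can be scored without field data.

The default geometry stands a 712-px inner frame square for 1 m² — close
to the 800-px working scale of the counting method, so the pipeline's
pixel-scale defaults apply unchanged.  Leaf ribbons default to ≈51–77 px
length and 5 px width (≈9 cm × 0.7 cm), with density spanning the
agronomic 75–300 plants/m² range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon

from .errors import SceneOverflowError
from .features import extract_features
from .io import RunConfig
from .rectify import Homography, Quadrangle, rectify_target_area, solve_perspective, warp_and_crop
from .segment import segment_seedlings

#: Relative leaf-size multipliers emulating seedling habit: lax cultivars
#: (HM7) spread more canopy per plant than erect ones (YF4).
VARIETY_SIZE_FACTOR = {"YM23": 1.00, "HM7": 1.12, "YF4": 0.92}

_SOIL = np.array([0.40, 0.29, 0.19])
_STRAW = np.array([0.74, 0.66, 0.50])
_FRAME = np.array([0.96, 0.96, 0.95])
_LEAF = np.array([0.14, 0.44, 0.12])


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``leaf_stage`` is the (possibly fractional) mean leaf age: a plant at
    stage 2.4 has two leaves with probability 0.6 and three with
    probability 0.4, and leaf length grows mildly with stage.
    ``frame_tilt`` bounds the random perspective distortion as a fraction
    of the canvas side.
    """

    n_plants: int = 150
    leaf_stage: float = 2.0
    leaf_length_px: tuple[float, float] = (64.0, 12.0)
    leaf_width_px: tuple[float, float] = (5.0, 1.0)
    curl_prob: float = 0.15
    straw_count: int = 25
    frame_tilt: float = 0.06
    seed: int = 0
    canvas_size: int = 960
    frame_margin: int = 96
    frame_band: int = 28

    def __post_init__(self) -> None:
        if self.n_plants < 0:
            raise ValueError("n_plants must be >= 0")
        if not 1.0 <= self.leaf_stage <= 3.0:
            raise ValueError("leaf_stage must lie in [1, 3]")
        for p in (self.curl_prob,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.frame_tilt <= 0.15:
            raise ValueError("frame_tilt must lie in [0, 0.15]")

    @property
    def inner_bounds(self) -> tuple[int, int]:
        lo = self.frame_margin + self.frame_band
        hi = self.canvas_size - lo
        return lo, hi


@dataclass(frozen=True)
class SceneTruth:
    """A rendered scene with its ground truth (all in scene coordinates)."""

    image: np.ndarray
    leaf_mask: np.ndarray
    frame_corners: Quadrangle
    n_plants: int
    per_plant_leaf_count: list[int]
    frame_mask: np.ndarray = field(repr=False, default=None)
    straw_mask: np.ndarray = field(repr=False, default=None)
    homography: Homography = None  # canonical -> scene


def _ribbon_polygon(points: np.ndarray, widths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polygon outline of a tapered ribbon along a sampled centerline."""
    tangents = np.gradient(points, axis=0)
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    norms[norms == 0] = 1.0
    normal = np.column_stack([-tangents[:, 1], tangents[:, 0]]) / norms[:, None]
    left = points + normal * widths[:, None] / 2.0
    right = points - normal * widths[:, None] / 2.0
    outline = np.vstack([left, right[::-1]])
    return outline[:, 0], outline[:, 1]


def _stamp(mask: np.ndarray, rr_poly: np.ndarray, cc_poly: np.ndarray,
           lo: int = 0, hi: int | None = None) -> None:
    hi = mask.shape[0] if hi is None else hi
    rr, cc = polygon(rr_poly, cc_poly, shape=mask.shape)
    keep = (rr >= lo) & (rr < hi) & (cc >= lo) & (cc < hi)
    mask[rr[keep], cc[keep]] = True


def _leaf_centerline(
    rng: np.random.Generator, base: np.ndarray, length: float
) -> np.ndarray:
    """Quadratic Bezier centerline from the plant base outward."""
    angle = rng.uniform(0, 2 * math.pi)
    direction = np.array([math.sin(angle), math.cos(angle)])
    tip = base + direction * length
    perp = np.array([-direction[1], direction[0]])
    ctrl = (base + tip) / 2 + perp * rng.normal(0, 0.2 * length)
    t = np.linspace(0, 1, max(8, int(2 * length)))[:, None]
    return ((1 - t) ** 2) * base + 2 * t * (1 - t) * ctrl + t**2 * tip


def _render_leaf(
    rng: np.random.Generator,
    leaf_mask: np.ndarray,
    base: np.ndarray,
    length: float,
    width: float,
    curled: bool,
    lo: int,
    hi: int,
) -> None:
    pts = _leaf_centerline(rng, base, length)
    t = np.linspace(0, 1, len(pts))
    # strap-shaped blade: constant width, then an apical taper to a sharp tip
    taper = np.where(t < 0.7, 1.0, 1.0 - 0.85 * (t - 0.7) / 0.3)
    widths = np.maximum(0.9, width * taper)
    if not curled:
        rr, cc = _ribbon_polygon(pts, widths)
        _stamp(leaf_mask, rr, cc, lo, hi)
        return
    # curl: fold the distal part back over the proximal part, slightly
    # offset — the footprint shrinks and a fold corner appears
    fold = rng.uniform(0.45, 0.70)
    i_fold = max(2, int(fold * len(pts)))
    proximal = pts[:i_fold]
    distal = pts[i_fold:]
    pivot = pts[i_fold - 1]
    mirrored = 2 * pivot - distal
    drift = (np.arange(len(distal)) / max(1, len(distal)))[:, None]
    tangent = pivot - pts[max(0, i_fold - 3)]
    perp = np.array([-tangent[1], tangent[0]])
    nrm = np.hypot(*perp)
    if nrm > 0:
        mirrored = mirrored + perp / nrm * drift * 0.15 * length
    for seg, wid in ((proximal, widths[:i_fold]), (mirrored, widths[i_fold:])):
        if len(seg) >= 2:
            rr, cc = _ribbon_polygon(seg, wid)
            _stamp(leaf_mask, rr, cc, lo, hi)


def _leaf_count(rng: np.random.Generator, stage: float) -> int:
    lower = math.floor(stage)
    frac = stage - lower
    n = lower + (1 if rng.random() < frac else 0)
    return int(min(3, max(1, n)))


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Render one scene; bit-deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    S = spec.canvas_size
    lo, hi = spec.inner_bounds
    interior_area = (hi - lo) ** 2
    if spec.n_plants > interior_area / 25:
        raise SceneOverflowError(
            f"{spec.n_plants} plants cannot be placed in {interior_area} px^2"
        )

    # --- canonical (fronto-parallel) scene -------------------------------
    image = np.empty((S, S, 3))
    lowfreq = ndimage.gaussian_filter(rng.normal(0, 1, (S, S)), sigma=S / 16)
    lowfreq = 0.05 * lowfreq / max(1e-9, np.abs(lowfreq).max())
    texture = 0.015 * rng.normal(0, 1, (S, S))
    for c, base in enumerate(_SOIL):
        image[..., c] = base * (1.0 + lowfreq + texture)

    straw_mask = np.zeros((S, S), dtype=bool)
    for _ in range(spec.straw_count):
        center = rng.uniform(spec.frame_margin // 2, S - spec.frame_margin // 2, 2)
        length = rng.uniform(18, 50) * S / 480
        pts = _leaf_centerline(rng, center, length)
        widths = np.full(len(pts), rng.uniform(1.5, 2.5))
        rr, cc = _ribbon_polygon(pts, widths)
        _stamp(straw_mask, rr, cc)
    shade = 1.0 + 0.04 * rng.normal(0, 1, (S, S))
    for c, base in enumerate(_STRAW):
        image[..., c] = np.where(straw_mask, base * shade, image[..., c])

    outer_lo, outer_hi = spec.frame_margin, S - spec.frame_margin
    frame_mask = np.zeros((S, S), dtype=bool)
    frame_mask[outer_lo:outer_hi, outer_lo:outer_hi] = True
    frame_mask[lo:hi, lo:hi] = False
    gloss = 1.0 + 0.01 * rng.normal(0, 1, (S, S))  # shared across channels:
    for c, base in enumerate(_FRAME):               # keeps r - b fixed
        image[..., c] = np.where(frame_mask, np.clip(base * gloss, 0, 1),
                                 image[..., c])

    leaf_mask = np.zeros((S, S), dtype=bool)
    per_plant: list[int] = []
    len_mu, len_sd = spec.leaf_length_px
    wid_mu, wid_sd = spec.leaf_width_px
    stage_factor = 0.8 + 0.2 * (spec.leaf_stage - 1.0)
    for _ in range(spec.n_plants):
        base_pt = rng.uniform(lo + 2, hi - 2, 2)
        n_leaves = _leaf_count(rng, spec.leaf_stage)
        per_plant.append(n_leaves)
        for _leaf in range(n_leaves):
            # nadir view foreshortens semi-erect blades: render the
            # projected length, blade length x cos(inclination)
            projection = rng.uniform(0.55, 0.95)
            length = max(8.0, rng.normal(len_mu * stage_factor, len_sd) * projection)
            width = max(2.0, rng.normal(wid_mu, wid_sd))
            curled = rng.random() < spec.curl_prob
            _render_leaf(rng, leaf_mask, base_pt, length, width, curled, lo, hi)
    brightness = 1.0 + 0.06 * ndimage.gaussian_filter(
        rng.normal(0, 1, (S, S)), sigma=S / 24
    )
    for c, base in enumerate(_LEAF):
        image[..., c] = np.where(leaf_mask, np.clip(base * brightness, 0, 1),
                                 image[..., c])
    image = np.clip(image, 0.0, 1.0)

    # --- perspective distortion -----------------------------------------
    s = S - 1
    canvas = Quadrangle(np.array([[0, 0], [0, s], [s, s], [s, 0]], dtype=float))
    jitter = rng.uniform(-spec.frame_tilt * S, spec.frame_tilt * S, (4, 2))
    warped = Quadrangle(canvas.corners + jitter)
    H = solve_perspective(canvas, warped)  # canonical -> scene

    Hinv_for_sampling = H  # warp_and_crop samples through H's inverse
    scene = warp_and_crop(image, Hinv_for_sampling, S)
    # extend border samples with soil rather than black
    out_of_range = warp_and_crop(np.ones((S, S)), H, S) < 0.5
    for c, base in enumerate(_SOIL):
        scene[..., c] = np.where(out_of_range, base, scene[..., c])
    scene = np.clip(scene, 0.0, 1.0)

    warp_mask = lambda m: warp_and_crop(m.astype(float), H, S) > 0.5
    inner = Quadrangle(
        np.array([[lo, lo], [lo, hi - 1], [hi - 1, hi - 1], [hi - 1, lo]],
                 dtype=float)
    )
    mapped = H.apply(inner.xy)[:, ::-1]  # back to (row, col)
    return SceneTruth(
        image=scene,
        leaf_mask=warp_mask(leaf_mask),
        frame_corners=Quadrangle(mapped),
        n_plants=spec.n_plants,
        per_plant_leaf_count=per_plant,
        frame_mask=warp_mask(frame_mask),
        straw_mask=warp_mask(straw_mask & ~frame_mask & ~leaf_mask),
        homography=H,
    )


#: Sowing densities of the emulated field experiment, in plants per m²
#: (the inner frame square stands for exactly 1 m²).
STUDY_DENSITIES = (75, 150, 225, 300)
STUDY_STAGES = (1, 2, 3)
STUDY_VARIETIES = ("YM23", "HM7", "YF4")


def study_design(
    seed: int, reps: int = 5
) -> tuple[list[SceneSpec], list[str]]:
    """Scene specs for the emulated field study.

    Full factorial over 4 sowing densities × 3 leaf stages × 3 varieties,
    ``reps`` replicates each; leaf age is jittered around the nominal
    stage (non-integer, as recorded in the field).  Returns the spec list
    and the aligned variety list for
    :func:`generate_observation_table`.
    """
    rng = np.random.default_rng(seed)
    specs: list[SceneSpec] = []
    varieties: list[str] = []
    for rep in range(reps):
        for variety in STUDY_VARIETIES:
            for stage in STUDY_STAGES:
                for density in STUDY_DENSITIES:
                    la = float(np.clip(stage + rng.uniform(-0.3, 0.3), 1.0, 3.0))
                    specs.append(
                        SceneSpec(
                            n_plants=density,
                            leaf_stage=la,
                            seed=int(rng.integers(0, 2**31 - 1)),
                        )
                    )
                    varieties.append(variety)
    return specs, varieties


def generate_observation_table(
    specs: list[SceneSpec],
    varieties: list[str],
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over generated scenes and tabulate features.

    Scene i is assigned ``varieties[i % len(varieties)]``; the variety's
    habit is emulated by scaling the leaf dimensions with
    :data:`VARIETY_SIZE_FACTOR`.  Columns: image_id, variety, La, stage,
    Co, Ha, SN_true.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    cfg = cfg or RunConfig()
    rows = []
    for i, spec in enumerate(specs):
        variety = varieties[i % len(varieties)]
        factor = VARIETY_SIZE_FACTOR.get(variety, 1.0)
        sized = SceneSpec(
            **{
                **spec.__dict__,
                "leaf_length_px": (spec.leaf_length_px[0] * factor,
                                   spec.leaf_length_px[1]),
                "leaf_width_px": (spec.leaf_width_px[0] * factor,
                                  spec.leaf_width_px[1]),
            }
        )
        try:
            truth = generate_scene(sized)
            rectified = rectify_target_area(truth.image, cfg)
            mask = segment_seedlings(rectified.image, cfg)
            fv = extract_features(mask, La=spec.leaf_stage, variety=variety,
                                  cfg=cfg)
        except Exception as exc:
            raise type(exc)(f"scene {i} (seed {spec.seed}): {exc}") from exc
        assert 0.0 <= fv.Co <= 1.0
        rows.append(
            dict(
                image_id=f"scene{i:04d}",
                variety=variety,
                La=spec.leaf_stage,
                stage=int(min(3, max(1, math.floor(spec.leaf_stage + 0.5)))),
                Co=fv.Co,
                Ha=fv.Ha,
                SN_true=spec.n_plants,
            )
        )
    return pd.DataFrame(rows)
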