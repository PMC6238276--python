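# Methods

This note documents the models and procedures implemented in
`seedlingcount`, the choices made where the published method leaves details
open, and what the synthetic test bed does and does not establish.

## Problem and pipeline

The package estimates the number of wheat seedlings (SN, plants per m²) at
the 1–3 leaf stage from a single nadir-ish RGB photograph of a stand in
which a white 1 m × 1 m frame marks the counting area. Direct per-plant
counting is unreliable once leaves overlap, so the method regresses SN on
two stand-level image features — coverage degree and a corner-point count —
plus two manually recorded covariates, leaf age and cultivar.

Stages:

1. **Rectification** (`rectify`). White-frame pixels are those with channel
   sum r+g+b > 2.1 and r−b < 0.05 on [0, 1]-normalized channels; the
   largest connected component is taken as the frame (specular highlights
   and small white debris also pass the thresholds, so the frame is assumed
   to be the largest white object). The frame band's *inner* contour is
   traced as a closed Freeman 8-direction chain code, and per-point
   curvature is computed as

       theta_i = |c_i − c_{i−1}|   (circular),
       phi_i   = theta_i            if theta_i ≤ 4, else 8 − theta_i,
       e_i     = phi_i (phi_{i−1} + phi_i + phi_{i+1}),

   which concentrates response on isolated direction changes and cancels
   the alternating ±1 jitter of digitized straight edges. The four corners
   are the four highest-e points subject to a pairwise arc-length
   separation of ≥ 10% of the perimeter. The perspective transform sending
   them to an axis-aligned square (default 800 × 800 px) is solved as the
   standard eight-unknown linear system from the four correspondences, and
   the photo is resampled by bilinear interpolation with zero fill.
2. **Segmentation** (`segment`). Excess green on chromatic coordinates
   (ExG = 1.8 g − r − b with r = R/(R+G+B) etc.), a 256-bin Otsu threshold,
   then a morphological opening (disk radius 1 at the 800-px scale) and
   filling of enclosed holes.
3. **Features** (`features`). Coverage degree Co = foreground fraction of
   the rectified area. Angular points Ha = count of suppressed local maxima
   of the Harris response R = det(M) − k·trace²(M) (k = 0.04) computed on
   the smoothed binary mask; leaf tips, leaf–leaf crossings and curl folds
   all produce such maxima.
4. **Models** (`models`). Nine per-cultivar, per-stage linear equations
   SN = β₁·Ha + β₂·Co + β₀, and one unified model
   SN = Va·(a·Ha + b·Co + c)/(d·La) with published defaults a = 0.44,
   b = 110.43, c = 3.35, d = 1.11 and variety coefficients
   Va(YM23) = 1.05, Va(HM7) = 0.86, Va(YF4) = 1.12. Negative predictions
   are clamped to zero with a warning flag.

## Design choices where the method description is open

* **Chain-code neighborhood.** The curvature formula is parameterized by a
  neighborhood size k; k = 8 is used, matching 8-connected Freeman coding of
  raster boundaries, so the index offset k/8 = 1 and phi ∈ [0, 4].
* **Corner validity gate.** The four-highest-e rule alone cannot reject a
  circle (every boundary point has small positive e). A candidate must
  additionally concentrate at least 2 chain-code units (≥ 90°) of *signed*
  turning inside a ±2-point window. A digital right-angle corner always
  passes; large-radius arcs and straight edges cancel to ≤ 1. The gate
  assumes frame corners stay within roughly ±30° of a right angle in the
  image — true for moderate camera tilt; extremely oblique views would need
  a larger window.
* **Inner vs outer contour.** The frame is a band; corners are taken on its
  inner contour because the counting area is the region the frame encloses.
* **Sub-pixel corner refinement.** Detected corner pixels carry half-pixel
  digitization error, which is visible after warping thin leaves. Each side
  of the quadrangle is refit by a total-least-squares line through the
  chain points between corners (10% trimmed at both ends) and corners are
  recomputed as line intersections. Refinement falls back to the pixel
  corners if it drifts by more than 4 px.
* **Chromatic ExG.** The excess-green coefficient set (1.8, −1, −1) is
  applied to sum-normalized channels, making segmentation exactly invariant
  to global brightness scaling. The 1.8 coefficient is used as published.
* **Otsu convention.** The threshold is the bin edge maximizing
  between-class variance over a 256-bin histogram spanning [min, max];
  foreground is strictly above the threshold. A constant map yields a
  warning and an empty mask rather than an error.
* **Harris detection knobs.** Only k is specified by the source method; the
  window scale (Gaussian σ = 1.5 px), relative threshold (1% of the peak
  response) and non-maximum-suppression radius (5 px at the 800-px scale)
  are engineering defaults exposed in `RunConfig`. The downstream linear
  calibration absorbs their scale.
* **Harris on the mask, not the photo.** Corners are detected on the
  segmented mask so soil texture and straw cannot contribute counts.
* **Stepwise regression.** Forward entry at p < 0.05 and backward removal
  at p > 0.10 by partial-F tests, final coefficients by ordinary least
  squares. On noiseless data the larger model's SSE is exactly zero; the
  partial-F p-value is then taken as 0, so both predictors enter and the
  published coefficients are recovered to machine precision.
* **Unified-model identifiability.** (a, b, c) and 1/d share a common
  scale, and so does the Va set: the model is invariant to
  (a,b,c,d) → (λa, λb, λc, λd). Fitting therefore requires fixing either
  d together with the Va table (then a, b, c come from OLS on the
  transformed predictors Va·Ha/(d·La), Va·Co/(d·La), Va/(d·La)) or all of
  (a, b, c, d) (then each cultivar's Va is a one-parameter projection).
* **REP.** Defined as 100·RMSE/mean(observed), with RMSE using the
  population denominator n.

## Synthetic scene generator

No image dataset accompanies the method, so `synth` renders scenes with
exact ground truth. A scene is composed in a fronto-parallel frame and then
warped by a bounded random homography (corner jitter ≤ 6% of the canvas by
default), exactly as a tilted camera would see it:

* **Geometry.** 960-px canvas; the frame band (28 px wide, white with
  shared-luminance gloss noise so r−b stays below 0.05) encloses a 712-px
  inner square standing for 1 m². 712 px/m is close to the method's 800-px
  working scale, so all pixel-scale defaults apply unchanged.
* **Background.** Brown soil (0.40, 0.29, 0.19) with low-frequency
  brightness undulation and per-pixel texture; ~25 pale straw ribbons with
  r−b ≈ 0.24 — deliberately close to white in luminance so the second
  frame-threshold condition is actually exercised.
* **Plants.** Placed uniformly in the frame interior. A plant at
  (possibly fractional) leaf stage s carries ⌊s⌋ or ⌈s⌉ leaves with the
  fractional probability. Each leaf is a quadratic-Bezier ribbon with a
  strap-shaped width profile (constant, then an apical taper to a sharp
  tip), default blade length 64 ± 12 px (≈ 9 cm) scaled mildly by stage,
  width 5 ± 1 px (≈ 0.7 cm). The rendered length is the blade length
  multiplied by a per-leaf projection factor cos(inclination) drawn from
  [0.55, 0.95], since a nadir camera forshortens semi-erect blades. With
  probability 0.15 a leaf is curled: its distal half is folded back over
  the proximal half with a small lateral drift, which lowers footprint and
  adds a fold corner — the curl signature.
* **Cultivar habit.** The three cultivars differ by seedling habit (lax >
  half-erect > erect ground cover per plant); this is emulated by leaf-size
  multipliers 1.12 (HM7, lax), 1.00 (YM23), 0.92 (YF4, erect), consistent
  in ordering with the published variety coefficients.
* **Study design.** `study_design` reproduces the emulated experiment:
  full factorial over sowing densities {75, 150, 225, 300} plants/m² ×
  leaf stages {1, 2, 3} × 3 cultivars, leaf age jittered ±0.3 around the
  nominal stage, five replicates (180 scenes; 120 for calibration, 60 held
  out).

**What the generator does not emulate:** shadows and specular soil
highlights, wind blur, lens distortion, mixed weed species, radiometric
camera response, and within-scene leaf-age heterogeneity. Tests passing on
these scenes therefore validate the pipeline's internal consistency and
its behavior under the geometric and photometric effects modelled — not
field-level accuracy.

## Numerical and degenerate-input behavior

Homographies are solved exactly for their four defining correspondences
(residual below 1e−9) and fail loudly for collinear points or singular
matrices. Empty masks, multi-component masks, chains shorter than the
curvature neighborhood, constant histograms, constant responses,
zero-variance observations and unknown cultivar names each raise a typed
error (or warn, where the pipeline can continue with an empty result).
Boundary tracing of a single pixel returns an empty closed chain. Ties in
corner selection and non-maximum suppression are broken by response value,
then scan order, so all results are deterministic; scene rendering is
bit-reproducible from its seed.

## Problem sizes used by the test suite

Unit tests render reduced scenes (480-px canvas, 356-px inner square) to
keep the suite fast; the end-to-end study runs the full 180-scene design at
the default 960-px scale and finishes in a few minutes on one core. On the
held-out 60 scenes the stage-wise calibration reaches R² ≈ 0.95 and
REP ≈ 9% (recomputed by `tests/test_acceptance.py` on every run).

## Known limitations

* The white-frame thresholds (2.1, 0.05) were tuned for particular field
  scenes; other cameras or lighting may need the exposed overrides.
* The corner gate assumes frame corners within ~±30° of a right angle in
  the image.
* Leaf age and cultivar are user-supplied; the package does not estimate
  them from imagery, and the unified model divides by leaf age, so errors
  in La propagate multiplicatively.
* The angular-point count depends on detector knobs the source method does
  not specify; calibrated coefficients are therefore only transferable
  between installations using the same `RunConfig`.
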