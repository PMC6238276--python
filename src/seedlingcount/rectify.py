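"""Target-area rectification via the white 1-m² reference frame.

A white square frame laid on the soil marks the counting area.  The stage
recovers a fronto-parallel view of the frame interior in four steps:

1. threshold the photo for white pixels (channel sum > 2.1 and
   r − b < 0.05 on [0, 1] channels) and keep the largest component;
2. trace the Freeman chain code of the frame's inner contour and locate its
   four corners as concentrated maxima of the chain-code curvature
   ``e_i = phi_i * (phi_{i-1} + phi_i + phi_{i+1})``;
3. solve the 3×3 perspective transform sending the four corners to the
   corners of an axis-aligned square (eight unknowns, a33 = 1);
4. resample the photo on the square grid by bilinear interpolation.

Coordinates are (row, col) everywhere except inside :class:`Homography`,
which works on (x, y) = (col, row) points as is conventional for projective
transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .errors import (
    BoundaryError,
    ChainTooShortError,
    CornersNotFoundError,
    DegenerateGeometryError,
    FrameNotFoundError,
    PipelineStageError,
)
from .io import RunConfig, as_rgb_image

# Freeman 8-direction codes: 0=E, then counterclockwise (1=NE, 2=N, ... 7=SE)
# in visual terms; rows grow downward so "N" is row-1.
CODE_TO_STEP = {
    0: (0, 1),
    1: (-1, 1),
    2: (-1, 0),
    3: (-1, -1),
    4: (0, -1),
    5: (1, -1),
    6: (1, 0),
    7: (1, 1),
}

# Codes in visually clockwise scan order starting at N; used by the Moore
# boundary-following neighbourhood scan.
_CLOCKWISE = (2, 1, 0, 7, 6, 5, 4, 3)
_CW_INDEX = {c: i for i, c in enumerate(_CLOCKWISE)}


@dataclass(frozen=True)
class ChainCode:
    """Closed Freeman chain code of a component's outer boundary."""

    start: tuple[int, int]
    codes: np.ndarray
    closed: bool = True

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of boundary pixels; points[i] precedes codes[i]."""
        if len(self.codes) == 0:
            return np.array([self.start])
        steps = np.array([CODE_TO_STEP[int(c)] for c in self.codes])
        pts = np.empty((len(self.codes), 2), dtype=int)
        pts[0] = self.start
        pts[1:] = self.start + np.cumsum(steps[:-1], axis=0)
        return pts


@dataclass(frozen=True)
class CurvatureProfile:
    """Per-boundary-point curvature: tangent change theta, folded angle phi
    in [0, k/2], and the corner response e = phi * (3-point phi sum)."""

    theta: np.ndarray
    phi: np.ndarray
    e: np.ndarray
    k: int = 8


@dataclass(frozen=True)
class Quadrangle:
    """Four (row, col) corners in canonical TL, TR, BR, BL order."""

    corners: np.ndarray

    def __post_init__(self) -> None:
        corners = np.asarray(self.corners, dtype=float)
        if corners.shape != (4, 2):
            raise DegenerateGeometryError(
                f"quadrangle needs 4 (row, col) corners, got shape {corners.shape}"
            )
        object.__setattr__(self, "corners", corners)
        if self.area() <= 0:
            raise DegenerateGeometryError("degenerate quadrangle (area <= 0)")

    @property
    def xy(self) -> np.ndarray:
        """Corners as (x, y) = (col, row) points."""
        return self.corners[:, ::-1]

    def area(self) -> float:
        x, y = self.corners[:, 1], self.corners[:, 0]
        return 0.5 * abs(
            np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
        )

    @classmethod
    def square(cls, size: int) -> "Quadrangle":
        s = size - 1
        return cls(np.array([[0, 0], [0, s], [s, s], [s, 0]], dtype=float))


@dataclass(frozen=True)
class Homography:
    """3×3 projective transform on (x, y) points, a33 fixed to 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise DegenerateGeometryError("homography matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise DegenerateGeometryError("singular transform")
        object.__setattr__(self, "matrix", m / m[2, 2])

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        homog = np.hstack([pts, np.ones((len(pts), 1))])
        mapped = homog @ self.matrix.T
        return mapped[:, :2] / mapped[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


@dataclass(frozen=True)
class RectifyResult:
    """Rectified target area plus the geometry that produced it."""

    image: np.ndarray
    corners: Quadrangle
    homography: Homography


def extract_white_quadrangle(
    img: np.ndarray, cfg: RunConfig | None = None
) -> np.ndarray:
    """Threshold for white-frame pixels and keep the largest component.

    A pixel belongs to the frame candidate set iff r + g + b > 2.1 and
    r − b < 0.05 (defaults; configurable).  Raises
    :class:`FrameNotFoundError` when the largest white component covers
    less than 0.1% of the image.
    """
    cfg = cfg or RunConfig()
    img = as_rgb_image(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    candidate = (r + g + b > cfg.frame_sum_min) & (r - b < cfg.frame_rb_max)
    labels, n = label(candidate, connectivity=2, return_num=True)
    if n == 0:
        raise FrameNotFoundError("no frame found: no white pixels")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < 0.001 * candidate.size:
        raise FrameNotFoundError(
            "no frame found: largest white component below 0.1% of image area"
        )
    return labels == best


def trace_boundary(mask: np.ndarray) -> ChainCode:
    """Clockwise Moore boundary trace of a single-component mask.

    The walk starts at the topmost (then leftmost) foreground pixel and
    returns a closed Freeman chain.  A single isolated pixel yields an
    empty, closed chain.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise BoundaryError("empty mask")
    _, n = label(mask, connectivity=2, return_num=True)
    if n > 1:
        raise BoundaryError(f"ambiguous boundary: {n} components")

    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    top = rows.min()
    start = (top, cols[rows == top].min())

    codes: list[int] = []
    current = start
    backtrack_code = 4  # the pixel west of the start is background
    while True:
        scan_from = _CW_INDEX[backtrack_code]
        move = None
        prev_bg = backtrack_code
        for offset in range(1, 9):
            code = _CLOCKWISE[(scan_from + offset) % 8]
            dr, dc = CODE_TO_STEP[code]
            if padded[current[0] + dr, current[1] + dc]:
                move = code
                break
            prev_bg = code
        if move is None:  # isolated pixel
            break
        if codes and current == start and move == codes[0]:
            break
        codes.append(move)
        dr, dc = CODE_TO_STEP[move]
        nxt = (current[0] + dr, current[1] + dc)
        # direction from the new pixel back to the last background neighbour
        pr, pc = CODE_TO_STEP[prev_bg]
        back = (current[0] + pr - nxt[0], current[1] + pc - nxt[1])
        backtrack_code = next(
            c for c, step in CODE_TO_STEP.items() if step == back
        )
        current = nxt

    return ChainCode(
        start=(start[0] - 1, start[1] - 1),
        codes=np.array(codes, dtype=int),
        closed=True,
    )


def curvature_profile(chain: ChainCode, k: int = 8) -> CurvatureProfile:
    """Chain-code curvature at every boundary point.

    At point i (incoming code ``c[i-1]``, outgoing ``c[i]``, circular),
    theta is the absolute code difference, phi folds it into [0, k/2], and
    ``e_i = phi_i * (phi_{i-1} + phi_i + phi_{i+1})`` concentrates the
    response on isolated direction changes — corners — while suppressing
    the alternating ±1 changes of digitized straight or gently curved
    edges.
    """
    codes = np.asarray(chain.codes, dtype=int)
    if len(codes) < k:
        raise ChainTooShortError(f"chain of length {len(codes)} shorter than k={k}")
    theta = np.abs(codes - np.roll(codes, 1))
    phi = np.where(theta <= k / 2, theta, k - theta).astype(float)
    e = phi * (np.roll(phi, 1) + phi + np.roll(phi, -1))
    return CurvatureProfile(theta=theta.astype(float), phi=phi, e=e, k=k)


def _signed_turn_window(codes: np.ndarray, half_width: int = 2) -> np.ndarray:
    """|sum of signed code changes| over a centered ±half_width window.

    The signed change at point i is the incoming→outgoing code difference
    wrapped into [-4, 3].  A genuine ~90° corner concentrates a total turn
    of magnitude 2 codes (90°/45°) into the window; digitization jitter on
    straight or large-radius boundaries cancels to at most 1.
    """
    diff = ((codes - np.roll(codes, 1) + 4) % 8) - 4
    total = np.zeros(len(codes), dtype=float)
    for j in range(-half_width, half_width + 1):
        total += np.roll(diff, -j)
    return np.abs(total)


def detect_frame_corners(
    profile: CurvatureProfile,
    chain: ChainCode,
    min_separation_frac: float = 0.10,
    min_turn: float = 2.0,
) -> Quadrangle:
    """Pick the frame's four corners from the curvature profile.

    Candidates are boundary points with positive corner response ``e`` whose
    windowed signed turn reaches ``min_turn`` chain codes (≥ 90° of real
    turning — this rejects circles and gentle arcs, which spread their
    turning evenly).  The four highest-``e`` candidates subject to a
    pairwise arc-length separation of ``min_separation_frac`` of the
    perimeter are returned in TL, TR, BR, BL order about the centroid.
    """
    n = len(chain)
    if n == 0:
        raise CornersNotFoundError("corners not found: degenerate boundary")
    points = chain.points
    turn = _signed_turn_window(np.asarray(chain.codes, dtype=int))
    valid = np.nonzero((profile.e > 0) & (turn >= min_turn))[0]
    if len(valid) == 0:
        raise CornersNotFoundError("corners not found: no concentrated curvature")
    order = valid[np.lexsort((valid, -profile.e[valid]))]

    min_sep = min_separation_frac * n
    kept: list[int] = []
    for idx in order:
        if all(
            min(abs(idx - j), n - abs(idx - j)) >= min_sep for j in kept
        ):
            kept.append(int(idx))
        if len(kept) == 4:
            break
    if len(kept) < 4:
        raise CornersNotFoundError(
            f"corners not found: only {len(kept)} separated curvature maxima"
        )

    corners = points[kept].astype(float)
    centroid = corners.mean(axis=0)
    angles = np.arctan2(corners[:, 0] - centroid[0], corners[:, 1] - centroid[1])
    # ascending atan2(drow, dcol) sweeps TL(-135°) → TR(-45°) → BR(45°) → BL(135°)
    return Quadrangle(corners[np.argsort(angles)])


def refine_quadrangle(chain: ChainCode, coarse: Quadrangle) -> Quadrangle:
    """Sub-pixel corner refinement by side-line intersection.

    The coarse corners are boundary pixels, so they carry half-pixel
    digitization error.  Each side of the quadrangle is re-estimated by a
    total-least-squares line through the chain points between consecutive
    corners (trimming 10% at each end to avoid corner rounding), and the
    refined corners are the intersections of adjacent side lines.  Falls
    back to the coarse corners when a side has too few points or adjacent
    sides are near-parallel.
    """
    points = chain.points.astype(float)
    n = len(points)
    idx = []
    for corner in coarse.corners:
        d2 = ((points - corner) ** 2).sum(axis=1)
        idx.append(int(np.argmin(d2)))
    order = np.argsort(idx)
    idx_sorted = [idx[i] for i in order]

    lines = []
    for a, b in zip(idx_sorted, np.roll(idx_sorted, -1)):
        span = (b - a) % n
        trim = max(1, int(0.1 * span))
        take = [(a + j) % n for j in range(trim, span - trim + 1)]
        if len(take) < 4:
            return coarse
        seg = points[take]
        centroid = seg.mean(axis=0)
        _, _, vt = np.linalg.svd(seg - centroid)
        direction = vt[0]
        lines.append((centroid, direction))

    refined = np.empty((4, 2))
    for i in range(4):
        (p1, d1) = lines[i - 1]  # side ending at corner i (cyclic)
        (p2, d2) = lines[i]
        A = np.column_stack([d1, -d2])
        if abs(np.linalg.det(A)) < 1e-9:
            return coarse
        t = np.linalg.solve(A, p2 - p1)
        refined[i] = p1 + t[0] * d1
    if np.abs(refined - points[idx_sorted]).max() > 4.0:
        return coarse  # refinement drifted; distrust it
    out = refined[np.argsort(order)]  # restore TL,TR,BR,BL order
    return Quadrangle(out)


def solve_perspective(src: Quadrangle, dst: Quadrangle) -> Homography:
    """Solve the perspective transform from four point correspondences.

    Sets up the standard eight-unknown linear system (a33 = 1) so that each
    source corner maps exactly to its destination corner.
    """
    s, d = src.xy, dst.xy
    for i in range(4):
        a = s[(i + 1) % 4] - s[i]
        b = s[(i + 2) % 4] - s[i]
        if abs(a[0] * b[1] - a[1] * b[0]) < 1e-9:
            raise DegenerateGeometryError(
                "degenerate correspondence: collinear source points"
            )
    rows, rhs = [], []
    for (x, y), (X, Y) in zip(s, d):
        rows.append([x, y, 1, 0, 0, 0, -X * x, -X * y])
        rhs.append(X)
        rows.append([0, 0, 0, x, y, 1, -Y * x, -Y * y])
        rhs.append(Y)
    try:
        h = np.linalg.solve(np.array(rows), np.array(rhs))
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"degenerate correspondence: {exc}") from exc
    return Homography(np.append(h, 1.0).reshape(3, 3))


def warp_and_crop(img: np.ndarray, H: Homography, size: int) -> np.ndarray:
    """Resample ``img`` onto a size×size grid under ``H``.

    ``H`` maps source (x, y) to destination; each output pixel is sampled
    from the inverse-mapped source location by bilinear interpolation, with
    zero fill outside the source raster.  Works on H×W×C images and 2-D
    rasters alike.
    """
    Hinv = H.inverse()
    ys, xs = np.mgrid[0:size, 0:size]
    src_xy = Hinv.apply(np.column_stack([xs.ravel(), ys.ravel()]))
    coords = np.array([src_xy[:, 1], src_xy[:, 0]])  # (row, col)

    arr = np.asarray(img, dtype=float)
    if arr.ndim == 2:
        out = ndimage.map_coordinates(arr, coords, order=1, cval=0.0)
        return out.reshape(size, size)
    channels = [
        ndimage.map_coordinates(arr[..., c], coords, order=1, cval=0.0).reshape(
            size, size
        )
        for c in range(arr.shape[2])
    ]
    return np.stack(channels, axis=-1)


def inner_contour_mask(frame_mask: np.ndarray) -> np.ndarray:
    """The frame interior: holes enclosed by the white band."""
    filled = ndimage.binary_fill_holes(frame_mask)
    interior = filled & ~frame_mask
    labels, n = label(interior, connectivity=1, return_num=True)
    if n == 0:
        raise FrameNotFoundError("no frame found: white component encloses no area")
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def rectify_target_area(img: np.ndarray, cfg: RunConfig | None = None) -> RectifyResult:
    """Full rectification: frame → corners → homography → square resample.

    Corners are taken on the frame band's *inner* contour, so the returned
    image is exactly the counting area enclosed by the frame.  Failures are
    re-raised as :class:`PipelineStageError` labelled with the stage that
    failed.
    """
    cfg = cfg or RunConfig()

    def run(stage, fn, *args):
        try:
            return fn(*args)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    frame = run("extract_white_quadrangle", extract_white_quadrangle, img, cfg)
    interior = run("extract_white_quadrangle", inner_contour_mask, frame)
    chain = run("trace_boundary", trace_boundary, interior)
    profile = run("curvature_profile", curvature_profile, chain)
    corners = run("detect_frame_corners", detect_frame_corners, profile, chain)
    corners = run("detect_frame_corners", refine_quadrangle, chain, corners)
    square = Quadrangle.square(cfg.target_size)
    H = run("solve_perspective", solve_perspective, corners, square)
    rectified = run("warp_and_crop", warp_and_crop, img, H, cfg.target_size)
    return RectifyResult(
        image=np.clip(rectified, 0.0, 1.0), corners=corners, homography=H
    )
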