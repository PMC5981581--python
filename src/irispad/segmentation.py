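"""Pupil and iris localization, and iris-ROI extraction.

The pipeline is the classical coarse-to-fine NIR iris localization:

1. *Sub-block template matching.*  Under NIR illumination the pupil is
   the darkest region of the eye, so the pupil box is found as the
   (x, y, s) maximizing ``sum_i (U_i - U_0)`` over a 3x3 tiling of s x s
   blocks — U_0 the mean gray level of the center block, U_1..U_8 the
   means of its eight neighbors — subject to U_0 being strictly smaller
   than every U_i.  Block means come from a summed-area table, so each
   candidate is O(1).

2. *Circular edge detection (CED).*  A Daugman-style integro-differential
   operator refines the boundaries: the circle (cx, cy, r) maximizing the
   absolute radial derivative of the mean intensity along the circle.
   The pupil uses the full circle; the iris limits the contour to the
   arcs -45..+30 degrees and 150..225 degrees (left/right iris-sclera
   boundary) to avoid eyelid and eyelash occlusion.  Candidate centers
   for both circles are pixels inside the pupil box.

3. *ROI cut.*  The square of side 2 * iris radius centered on the iris is
   cropped (edge-padded if it leaves the image), bilinearly rescaled to
   224 x 224, and duplicated into three identical channels for the
   convolutional feature extractor.

Coordinates are 0-based with x = column, y = row; angles are measured
counterclockwise from the +x axis (so the y-coordinate of a contour
sample is ``cy - r*sin(theta)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.transform import resize

from irispad._interp import bilinear
from irispad.errors import DetectionFailure, GeometryError, ValidationError
from irispad.synth import Circle

#: default iris contour arcs (radians): -45..+30 and 150..225 degrees
IRIS_ARCS = ((-math.pi / 4, math.pi / 6), (5 * math.pi / 6, 5 * math.pi / 4))
FULL_CIRCLE = ((0.0, 2 * math.pi),)


@dataclass(frozen=True)
class PupilBox:
    """Pupil candidate found by sub-block template matching."""

    x: float  # center of the winning s x s block (pixel units)
    y: float
    s: int  # block side length
    score: float  # value of the template objective sum_i (U_i - U_0)

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """Integer (x0, y0, x1, y1) of the center block (x1/y1 exclusive)."""
        x0 = int(round(self.x - (self.s - 1) / 2))
        y0 = int(round(self.y - (self.s - 1) / 2))
        return x0, y0, x0 + self.s, y0 + self.s


@dataclass
class SegmentationResult:
    pupil: Circle
    iris: Circle
    roi: np.ndarray  # (roi_size, roi_size, 3), three identical channels


@dataclass(frozen=True)
class SegConfig:
    """Segmentation search parameters.

    ``s_range`` defaults to image_height/20 .. image_height/5 swept in
    4-px steps; ``pupil_r_range`` to 2 .. min(w,h)/5.  The iris radius
    search starts at ``iris_r_factor * pupil.r`` to enforce the
    pupil-inside-iris ordering with a margin.
    """

    s_range: tuple[int, int] | None = None
    s_step: int = 4
    pupil_stride: int = 2
    ced_center_stride: int = 2
    n_samples: int = 256
    smooth_sigma: float = 1.0
    pupil_r_range: tuple[int, int] | None = None
    iris_r_range: tuple[int, int] | None = None
    iris_r_factor: float = 1.1
    iris_arcs: tuple[tuple[float, float], ...] = IRIS_ARCS
    roi_size: int = 224


def integral_image(image: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero guard row/column.

    Integer-valued inputs are accumulated in int64, so rectangle sums are
    exact.
    """
    a = np.asarray(image)
    if a.ndim != 2 or a.size == 0:
        raise ValidationError("integral_image requires a non-empty 2-D image")
    if np.issubdtype(a.dtype, np.integer):
        a = a.astype(np.int64)
    else:
        rounded = np.round(a)
        a = rounded.astype(np.int64) if np.array_equal(a, rounded) else a.astype(np.float64)
    sat = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=a.dtype)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=sat[1:, 1:])
    return sat


def rect_sum(sat: np.ndarray, y0, x0, height: int, width: int):
    """Sum of the rectangle with top-left (y0, x0), given side lengths.

    ``y0``/``x0`` may be arrays; the query is O(1) per rectangle.
    """
    y0 = np.asarray(y0)
    x0 = np.asarray(x0)
    return (
        sat[y0 + height, x0 + width]
        - sat[y0, x0 + width]
        - sat[y0 + height, x0]
        + sat[y0, x0]
    )


def _pupil_scan(
    sat: np.ndarray,
    s: int,
    bx: np.ndarray,
    by: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Objective and validity for center-block top-left positions (by, bx)."""
    byg, bxg = np.meshgrid(by, bx, indexing="ij")
    u0 = rect_sum(sat, byg, bxg, s, s).astype(np.float64)
    total = np.zeros_like(u0)
    valid = np.ones(u0.shape, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ui = rect_sum(sat, byg + di * s, bxg + dj * s, s, s).astype(np.float64)
            total += ui - u0
            valid &= u0 < ui
    return total / (s * s), valid


def detect_pupil(
    image: np.ndarray,
    s_range: tuple[int, int] | None = None,
    stride: int = 2,
    s_step: int = 4,
    refine: bool = True,
) -> PupilBox:
    """Locate the pupil block by sub-block template matching.

    Returns the grid argmax of ``sum_i (U_i - U_0)`` (in mean-gray-level
    units) over all candidate positions and block sizes whose center
    block is strictly darker than all eight neighbors.  Ties break toward
    the smallest s, then lexicographic (y, x).  With ``refine`` a
    stride-1 pass re-scans a window around the coarse argmax.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if s_range is None:
        s_range = (max(2, h // 20), max(3, h // 5))
    s_lo, s_hi = s_range
    if s_lo < 1 or 3 * s_lo > min(h, w):
        raise ValidationError(f"s_range {s_range} infeasible for {w}x{h} image")
    sat = integral_image(image)

    best: tuple[float, int, int, int] | None = None  # (score, s, by, bx)

    def scan(s: int, bys: np.ndarray, bxs: np.ndarray) -> None:
        nonlocal best
        if len(bys) == 0 or len(bxs) == 0:
            return
        score, valid = _pupil_scan(sat, s, bxs, bys)
        if not valid.any():
            return
        masked = np.where(valid, score, -np.inf)
        idx = np.unravel_index(np.argmax(masked), masked.shape)
        sc = masked[idx]
        if best is None or sc > best[0]:
            best = (float(sc), s, int(bys[idx[0]]), int(bxs[idx[1]]))

    sizes = [s for s in range(s_lo, s_hi + 1, s_step) if 3 * s <= min(h, w)]
    for s in sizes:
        scan(s, np.arange(s, h - 2 * s + 1, stride), np.arange(s, w - 2 * s + 1, stride))

    if best is not None and refine and stride > 1:
        _, s, by, bx = best
        bys = np.arange(max(s, by - stride), min(h - 2 * s, by + stride) + 1)
        bxs = np.arange(max(s, bx - stride), min(w - 2 * s, bx + stride) + 1)
        scan(s, bys, bxs)

    if best is None:
        raise DetectionFailure(
            "no block was strictly darker than all eight neighbors"
        )
    score, s, by, bx = best
    return PupilBox(x=bx + (s - 1) / 2, y=by + (s - 1) / 2, s=s, score=score)


def _arc_angles(
    arcs: tuple[tuple[float, float], ...], n_samples: int
) -> np.ndarray:
    """Equi-angular midpoint samples over the given arcs.

    ``n_samples`` is the density for a full circle; each arc receives a
    proportional share (at least 8 points).
    """
    if not arcs:
        raise ValidationError("arcs must be non-empty")
    thetas = []
    for a0, a1 in arcs:
        if a1 <= a0:
            raise ValidationError(f"degenerate arc ({a0}, {a1})")
        n = max(8, int(round(n_samples * (a1 - a0) / (2 * math.pi))))
        k = np.arange(n) + 0.5
        thetas.append(a0 + k * (a1 - a0) / n)
    return np.concatenate(thetas)


def circular_mean(
    image: np.ndarray,
    circle: Circle,
    arcs: tuple[tuple[float, float], ...] = FULL_CIRCLE,
    n_samples: int = 256,
) -> float:
    """Mean bilinearly interpolated intensity along circle arcs."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if n_samples < 8:
        raise ValidationError("n_samples must be >= 8")
    if (
        circle.cx + circle.r < 0
        or circle.cx - circle.r > w - 1
        or circle.cy + circle.r < 0
        or circle.cy - circle.r > h - 1
    ):
        raise GeometryError("circle lies entirely outside the image")
    th = _arc_angles(arcs, n_samples)
    xs = circle.cx + circle.r * np.cos(th)
    ys = circle.cy - circle.r * np.sin(th)
    return float(bilinear(image, xs, ys).mean())


def _radial_profile(
    image: np.ndarray,
    cx: float,
    cy: float,
    radii: np.ndarray,
    thetas: np.ndarray,
) -> np.ndarray:
    """circular_mean at every radius (vectorized over the radius grid)."""
    xs = cx + radii[:, None] * np.cos(thetas)[None, :]
    ys = cy - radii[:, None] * np.sin(thetas)[None, :]
    return bilinear(image, xs, ys).mean(axis=1)


def ced(
    image: np.ndarray,
    center_candidates,
    r_range: tuple[int, int],
    arcs: tuple[tuple[float, float], ...] = FULL_CIRCLE,
    smooth_sigma: float = 1.0,
    n_samples: int = 256,
) -> Circle:
    """Circular edge detection: maximize |d/dr of the circular mean|.

    The radial profile is evaluated on a unit-radius grid, optionally
    Gaussian-smoothed along r, and differentiated by central finite
    differences.  Ties break toward the smallest radius, then
    lexicographic (cy, cx).
    """
    image = np.asarray(image, dtype=np.float64)
    centers = sorted((float(cy), float(cx)) for cx, cy in center_candidates)
    if not centers:
        raise ValidationError("empty center candidate set")
    r_lo, r_hi = r_range
    if r_lo <= 0 or r_hi < r_lo:
        raise ValidationError(f"invalid radius range {r_range}")
    radii = np.arange(r_lo, r_hi + 1, dtype=np.float64)
    thetas = _arc_angles(arcs, n_samples)

    best: tuple[float, float, float, float] | None = None  # (obj, r, cy, cx)
    for cy, cx in centers:
        prof = _radial_profile(image, cx, cy, radii, thetas)
        if smooth_sigma > 0:
            prof = gaussian_filter1d(prof, smooth_sigma, mode="nearest")
        deriv = np.abs(np.gradient(prof, radii))
        i = int(np.argmax(deriv))  # first max -> smallest radius on ties
        if best is None or deriv[i] > best[0]:
            best = (float(deriv[i]), float(radii[i]), cy, cx)
    assert best is not None
    _, r, cy, cx = best
    return Circle(cx=cx, cy=cy, r=r)


def _box_centers(
    box: PupilBox, image_shape: tuple[int, int], stride: int
) -> list[tuple[int, int]]:
    h, w = image_shape
    x0, y0, x1, y1 = box.bounds
    xs = range(max(0, x0), min(w, x1), stride)
    ys = range(max(0, y0), min(h, y1), stride)
    return [(x, y) for y in ys for x in xs]


def extract_roi(
    image: np.ndarray, iris: Circle, roi_size: int = 224
) -> np.ndarray:
    """Cut the square of side 2r around the iris and rescale to roi_size.

    The crop is edge-padded where it leaves the image; the rescaled gray
    patch is duplicated into three identical channels.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    side = max(2, int(round(2 * iris.r)))
    x0 = int(round(iris.cx - iris.r))
    y0 = int(round(iris.cy - iris.r))
    pad_l = max(0, -x0)
    pad_t = max(0, -y0)
    pad_r = max(0, x0 + side - w)
    pad_b = max(0, y0 + side - h)
    patch = np.pad(image, ((pad_t, pad_b), (pad_l, pad_r)), mode="edge")[
        y0 + pad_t : y0 + pad_t + side, x0 + pad_l : x0 + pad_l + side
    ]
    roi = resize(
        patch, (roi_size, roi_size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.stack([roi, roi, roi], axis=-1)


def segment(image: np.ndarray, config: SegConfig | None = None) -> SegmentationResult:
    """Full localization: pupil box -> pupil circle -> iris circle -> ROI."""
    if config is None:
        config = SegConfig()
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape

    box = detect_pupil(
        image, s_range=config.s_range, stride=config.pupil_stride,
        s_step=config.s_step,
    )
    centers = _box_centers(box, (h, w), config.ced_center_stride)

    pupil_r_range = config.pupil_r_range or (2, max(3, min(h, w) // 5))
    pupil = ced(
        image, centers, pupil_r_range, arcs=FULL_CIRCLE,
        smooth_sigma=config.smooth_sigma, n_samples=config.n_samples,
    )

    iris_r_lo = max(
        int(math.ceil(config.iris_r_factor * pupil.r)), int(pupil.r) + 2
    )
    iris_r_hi = (
        config.iris_r_range[1] if config.iris_r_range else min(h, w) // 2 - 2
    )
    if config.iris_r_range:
        iris_r_lo = max(iris_r_lo, config.iris_r_range[0])
    if iris_r_hi < iris_r_lo:
        raise DetectionFailure(
            f"iris radius search range empty ({iris_r_lo}..{iris_r_hi})"
        )
    iris = ced(
        image, centers, (iris_r_lo, iris_r_hi), arcs=config.iris_arcs,
        smooth_sigma=config.smooth_sigma, n_samples=config.n_samples,
    )

    roi = extract_roi(image, iris, config.roi_size)
    return SegmentationResult(pupil=pupil, iris=iris, roi=roi)
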