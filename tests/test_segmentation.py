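"""Segmentation: integral image, pupil template matching, circular edge
detection, and the full localization pipeline, each against an
independent brute-force oracle where the search is non-trivial."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.ndimage import gaussian_filter1d

from irispad import synth
from irispad.errors import DetectionFailure, GeometryError, ValidationError
from irispad.segmentation import (
    FULL_CIRCLE,
    SegConfig,
    ced,
    circular_mean,
    detect_pupil,
    integral_image,
    rect_sum,
    segment,
)
from irispad.synth import Circle


class TestIntegralImage:
    def test_all_ones_full_rectangle(self):
        sat = integral_image(np.ones((4, 4)))
        assert rect_sum(sat, 0, 0, 4, 4) == 16

    def test_single_cell(self):
        sat = integral_image(np.array([[7.0]]))
        assert rect_sum(sat, 0, 0, 1, 1) == 7

    def test_random_rectangles_match_brute_force(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (8, 8))
        sat = integral_image(img)
        for _ in range(100):
            y0, x0 = rng.integers(0, 8, 2)
            h = rng.integers(1, 9 - y0)
            w = rng.integers(1, 9 - x0)
            assert rect_sum(sat, y0, x0, h, w) == img[y0 : y0 + h, x0 : x0 + w].sum()

    @given(
        hnp.arrays(np.int64, hnp.array_shapes(min_dims=2, max_dims=2, max_side=12),
                   elements=st.integers(0, 255))
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_rectangle_sums_exact_property(self, img):
        sat = integral_image(img)
        h, w = img.shape
        assert rect_sum(sat, 0, 0, h, w) == img.sum()
        assert rect_sum(sat, 0, 0, (h + 1) // 2, (w + 1) // 2) == img[
            : (h + 1) // 2, : (w + 1) // 2
        ].sum()


def _brute_force_pupil(image, sizes, stride=1):
    """Literal re-evaluation of the sub-block objective with loops."""
    h, w = image.shape
    best = None  # (score, s, by, bx)
    for s in sizes:
        for by in range(s, h - 2 * s + 1, stride):
            for bx in range(s, w - 2 * s + 1, stride):
                u0 = image[by : by + s, bx : bx + s].mean()
                total = 0.0
                ok = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ui = image[
                            by + di * s : by + (di + 1) * s,
                            bx + dj * s : bx + (dj + 1) * s,
                        ].mean()
                        total += ui - u0
                        ok = ok and (u0 < ui)
                if ok and (best is None or total > best[0]):
                    best = (total, s, by, bx)
    return best


class TestDetectPupil:
    def test_center_close_to_ground_truth(self, eye_and_truth):
        img, gt = eye_and_truth
        box = detect_pupil(img, stride=1)
        assert abs(box.x - gt.pupil.cx) <= box.s / 2
        assert abs(box.y - gt.pupil.cy) <= box.s / 2

    def test_uniform_image_fails(self):
        with pytest.raises(DetectionFailure):
            detect_pupil(np.full((60, 60), 80.0))

    def test_matches_brute_force_on_64x64(self):
        rng = np.random.default_rng(7)
        img = np.full((64, 64), 180.0) + rng.normal(0, 4, (64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        img[np.hypot(xx - 30, yy - 33) <= 9] = 40.0
        sizes = [s for s in range(3, 13, 4)]
        oracle = _brute_force_pupil(img, sizes, stride=1)
        box = detect_pupil(img, s_range=(3, 12), stride=1, s_step=4)
        assert oracle is not None
        _, s, by, bx = oracle
        assert box.s == s
        assert box.x == bx + (s - 1) / 2
        assert box.y == by + (s - 1) / 2

    def test_gray_shift_leaves_argmax_unchanged(self, eye_and_truth):
        img, _ = eye_and_truth
        a = detect_pupil(img)
        b = detect_pupil(img + 17.0)
        assert (a.x, a.y, a.s) == (b.x, b.y, b.s)


class TestCircularMean:
    def test_constant_image(self):
        img = np.full((50, 50), 93.0)
        assert circular_mean(img, Circle(25, 25, 10)) == pytest.approx(93.0)

    def test_half_plane_average(self):
        img = np.zeros((80, 80))
        img[:, 40:] = 200.0
        # center on the black/white boundary: half the contour on each side
        m = circular_mean(img, Circle(40, 40, 15))
        assert m == pytest.approx(100.0, abs=4.0)

    def test_sampling_refinement_converges(self, eye_and_truth):
        img, gt = eye_and_truth
        circle = Circle(gt.iris.cx, gt.iris.cy, gt.iris.r + 4)
        coarse = circular_mean(img, circle, n_samples=256)
        fine = circular_mean(img, circle, n_samples=1024)
        assert abs(coarse - fine) < 0.5

    def test_outside_circle_rejected(self):
        with pytest.raises(GeometryError):
            circular_mean(np.zeros((20, 20)), Circle(100, 100, 5))


def _brute_force_ced(image, centers, radii, arcs, smooth_sigma, n_samples):
    """Independent re-evaluation: per-circle circular means via loops."""
    best = None
    for cy, cx in sorted((cy, cx) for cx, cy in centers):
        prof = []
        for r in radii:
            prof.append(circular_mean(image, Circle(cx, cy, r), arcs, n_samples))
        prof = np.array(prof)
        if smooth_sigma > 0:
            prof = gaussian_filter1d(prof, smooth_sigma, mode="nearest")
        deriv = np.abs(np.gradient(prof, np.asarray(radii, dtype=float)))
        i = int(np.argmax(deriv))
        if best is None or deriv[i] > best[0]:
            best = (deriv[i], radii[i], cy, cx)
    return best


def _disc_image(size, cx, cy, r, inside=50.0, outside=200.0):
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.full((size, size), outside)
    img[np.hypot(xx - cx, yy - cy) <= r] = inside
    return img


class TestCed:
    def test_recovers_disc_radius(self):
        img = _disc_image(100, 49, 51, 30)
        found = ced(img, [(49, 51)], (20, 40))
        assert abs(found.r - 30) <= 1

    def test_rotation_invariance_full_circle(self):
        img = _disc_image(100, 40, 55, 22)
        rot = np.rot90(img)
        a = ced(img, [(40, 55)], (15, 30))
        # rot90 maps (x, y) -> (y, N-1-x)
        b = ced(rot, [(55, 100 - 1 - 40)], (15, 30))
        assert a.r == b.r

    def test_matches_brute_force_grid(self):
        img = _disc_image(64, 31, 30, 18)
        centers = [(x, y) for x in range(29, 34) for y in range(28, 33)]
        found = ced(img, centers, (12, 24), n_samples=128)
        oracle = _brute_force_ced(
            img, centers, list(range(12, 25)), FULL_CIRCLE, 1.0, 128
        )
        assert (found.r, found.cy, found.cx) == (oracle[1], oracle[2], oracle[3])

    def test_gray_shift_leaves_maximizer_unchanged(self):
        img = _disc_image(80, 40, 40, 25)
        a = ced(img, [(40, 40), (41, 40)], (18, 32))
        b = ced(img + 30.0, [(40, 40), (41, 40)], (18, 32))
        assert (a.cx, a.cy, a.r) == (b.cx, b.cy, b.r)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValidationError):
            ced(np.zeros((20, 20)), [], (3, 6))


class TestSegment:
    def test_recovers_synthetic_geometry(self, eye_and_truth):
        img, gt = eye_and_truth
        res = segment(img)
        assert abs(res.pupil.r - gt.pupil.r) <= 2
        assert abs(res.iris.r - gt.iris.r) <= 2
        assert math.hypot(res.pupil.cx - gt.pupil.cx, res.pupil.cy - gt.pupil.cy) <= 2
        assert math.hypot(res.iris.cx - gt.iris.cx, res.iris.cy - gt.iris.cy) <= 2

    def test_roi_shape_and_channel_duplication(self, eye_and_truth):
        img, _ = eye_and_truth
        res = segment(img)
        assert res.roi.shape == (224, 224, 3)
        assert np.array_equal(res.roi[..., 0], res.roi[..., 1])
        assert np.array_equal(res.roi[..., 0], res.roi[..., 2])

    def test_radius_ordering_holds_over_seeds(self, default_params):
        for seed in range(12):
            img, _ = synth.generate_eye(default_params, seed)
            res = segment(img)
            assert res.pupil.r < res.iris.r

    def test_custom_roi_size(self, eye_and_truth):
        img, _ = eye_and_truth
        res = segment(img, SegConfig(roi_size=64))
        assert res.roi.shape == (64, 64, 3)

    def test_arc_limited_iris_survives_eyelid_occlusion(self, default_params):
        # the iris arcs avoid the top of the circle, so a bright eyelid
        # band clipping the upper iris must not disturb the radius
        params = replace(default_params, eyelid_occlusion=True)
        for seed in range(5):
            img, gt = synth.generate_eye(params, seed)
            res = segment(img)
            assert abs(res.iris.r - gt.iris.r) <= 3
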