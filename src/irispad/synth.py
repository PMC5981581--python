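"""Synthetic NIR-like eye images with known ground-truth geometry.

Real benchmark PAD datasets are distributed under request-gated licenses,
so every pipeline stage here is exercised against generated eyes instead:
a dark circular pupil, an iris annulus carrying band-limited radial and
angular texture, and a brighter sclera/skin surround — the intensity
ordering pupil < iris < sclera that NIR illumination produces.  Attack
variants emulate the artifacts of recaptured prints and textured contact
lenses: salt-like printing-dot noise, optical blur, and a coarse
quantization of the iris texture ("broken texture").
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from irispad.errors import ValidationError
from irispad.io_manifest import DatasetRecord


@dataclass(frozen=True)
class Circle:
    """Circle in pixel coordinates: 0-based, x = column, y = row."""

    cx: float
    cy: float
    r: float


@dataclass(frozen=True)
class EyeGroundTruth:
    pupil: Circle
    iris: Circle
    label: str
    seed: int


@dataclass(frozen=True)
class SynthParams:
    """Generator settings.

    Intensity levels are ordered ``pupil < iris_base < sclera`` as in NIR
    imagery.  ``attack_dot_density`` is the fraction of pixels flipped to
    bright printing dots; ``attack_blur_sigma`` the Gaussian blur radius in
    px; ``attack_quant_levels`` the number of intensity levels the iris
    texture is crushed to (0 disables quantization).
    """

    image_size: tuple[int, int] = (160, 120)  # (width, height)
    pupil_radius_range: tuple[float, float] = (10.0, 16.0)
    iris_radius_range: tuple[float, float] = (30.0, 45.0)
    intensity_levels: tuple[float, float, float] = (30.0, 110.0, 200.0)
    texture_amplitude: float = 25.0
    noise_sd: float = 3.0
    attack_dot_density: float = 0.03
    attack_blur_sigma: float = 1.0
    attack_quant_levels: int = 4
    eyelid_occlusion: bool = False

    def __post_init__(self) -> None:
        w, h = self.image_size
        if self.pupil_radius_range[1] >= self.iris_radius_range[0]:
            raise ValidationError("pupil radius range must lie below iris range")
        p, i, s = self.intensity_levels
        if not (p < i < s):
            raise ValidationError("intensity levels must satisfy pupil < iris < sclera")
        if 2 * self.iris_radius_range[1] >= min(w, h):
            raise ValidationError(
                f"iris radius range infeasible for image size {w}x{h}"
            )
        if not 0.0 <= self.attack_dot_density <= 1.0:
            raise ValidationError("attack_dot_density must be in [0, 1]")


def generate_eye(
    params: SynthParams, seed: int
) -> tuple[np.ndarray, EyeGroundTruth]:
    """Generate one bona-fide eye image and its ground-truth geometry.

    Deterministic for a fixed seed.  The iris texture is a sum of 3–6
    random-phase sinusoids in polar coordinates plus white noise, which
    gives fine radial structure comparable to what LBP operators respond
    to in real irides.
    """
    w, h = params.image_size
    rng = np.random.default_rng(seed)

    iris_r = rng.uniform(*params.iris_radius_range)
    pupil_r = rng.uniform(*params.pupil_radius_range)
    margin = iris_r + 3
    cx = w / 2 + rng.uniform(-5, 5)
    cy = h / 2 + rng.uniform(-5, 5)
    cx = float(np.clip(cx, margin, w - 1 - margin))
    cy = float(np.clip(cy, margin, h - 1 - margin))
    # pupil center may be slightly off the iris center but stays well inside
    max_off = min(2.0, 0.4 * (iris_r - pupil_r))
    px = cx + rng.uniform(-max_off, max_off)
    py = cy + rng.uniform(-max_off, max_off)

    lv_pupil, lv_iris, lv_sclera = params.intensity_levels
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d_iris = np.hypot(xx - cx, yy - cy)
    d_pupil = np.hypot(xx - px, yy - py)

    img = np.full((h, w), lv_sclera, dtype=np.float64)

    iris_mask = d_iris <= iris_r
    if params.texture_amplitude > 0:
        phi = np.arctan2(cy - yy, xx - cx)
        n_waves = rng.integers(3, 7)
        tex = np.zeros_like(img)
        for _ in range(n_waves):
            k_ang = rng.integers(4, 17)
            k_rad = rng.uniform(0.3, 1.2)
            phase = rng.uniform(0, 2 * np.pi)
            tex += np.sin(k_ang * phi + k_rad * d_iris + phase)
        tex /= n_waves
        img[iris_mask] = lv_iris + params.texture_amplitude * tex[iris_mask]
    else:
        img[iris_mask] = lv_iris

    pupil_mask = d_pupil <= pupil_r
    img[pupil_mask] = lv_pupil

    if params.noise_sd > 0:
        # spatially smooth shading noise: a live capture varies in
        # illumination but keeps its fine texture clean, so the noise
        # field is low-pass — per-pixel white noise would flood the
        # non-uniform LBP bins of the bona-fide class
        field = gaussian_filter(rng.normal(0.0, 1.0, size=img.shape), 1.0)
        img += params.noise_sd * field / field.std()

    if params.eyelid_occlusion:
        lid_y = int(cy - 0.6 * iris_r)
        img[: max(lid_y, 0), :] = lv_sclera

    np.clip(img, 0, 255, out=img)
    gt = EyeGroundTruth(
        pupil=Circle(px, py, pupil_r),
        iris=Circle(cx, cy, iris_r),
        label="bona_fide",
        seed=seed,
    )
    return img, gt


def make_attack(
    image: np.ndarray,
    params: SynthParams,
    seed: int,
    gt: EyeGroundTruth | None = None,
) -> np.ndarray:
    """Turn a bona-fide synthetic eye into a presentation-attack variant.

    Applies, in order: Gaussian blur at ``attack_blur_sigma`` (loss of
    fine detail in the printed pattern), a coarse intensity quantization
    of the iris texture (limited tonal depth of the print; restricted to
    the iris annulus when ground truth is supplied, otherwise applied
    image-wide), fresh capture shading noise (the attack is recaptured
    by the same sensor, so its noise floor matches a live capture's),
    and salt-like dot noise at ``attack_dot_density`` — the printing
    raster, observed sharply on top of the recaptured pattern.  The eye
    geometry is unchanged.
    """
    if not 0.0 <= params.attack_dot_density <= 1.0:
        raise ValidationError("attack_dot_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=np.float64).copy()
    h, w = out.shape

    if params.attack_blur_sigma > 0:
        out = gaussian_filter(out, params.attack_blur_sigma, mode="nearest")

    if params.attack_quant_levels and params.attack_quant_levels > 1:
        if gt is not None:
            yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
            region = (
                np.hypot(xx - gt.iris.cx, yy - gt.iris.cy) <= gt.iris.r
            ) & (np.hypot(xx - gt.pupil.cx, yy - gt.pupil.cy) > gt.pupil.r)
        else:
            region = np.ones((h, w), dtype=bool)
        vals = out[region]
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            q = params.attack_quant_levels
            idx = np.minimum((vals - lo) / (hi - lo) * q, q - 1).astype(int)
            out[region] = lo + (idx + 0.5) * (hi - lo) / q

    if params.noise_sd > 0 and params.attack_blur_sigma > 0:
        # restore the capture noise floor the blur suppressed
        field = gaussian_filter(rng.normal(0.0, 1.0, size=out.shape), 1.0)
        out += params.noise_sd * field / field.std()

    if params.attack_dot_density > 0:
        dots = rng.random((h, w)) < params.attack_dot_density
        out[dots] = 255.0
    return out


def generate_dataset(
    params: SynthParams,
    n_real: int,
    n_attack: int,
    seed: int,
    unknown_style: bool = False,
) -> tuple[list[np.ndarray], list[DatasetRecord], list[EyeGroundTruth]]:
    """Generate a labelled synthetic dataset with manifest and ground truth.

    Splits alternate train / test_known within each class.  With
    ``unknown_style=True`` the attack images are instead produced with
    doubled blur and assigned to test_unknown, emulating the domain shift
    of a different capture device or attack instrument.
    """
    if n_real < 0 or n_attack < 0:
        raise ValidationError("counts must be non-negative")
    images: list[np.ndarray] = []
    records: list[DatasetRecord] = []
    truths: list[EyeGroundTruth] = []

    attack_params = params
    if unknown_style:
        attack_params = replace(
            params, attack_blur_sigma=2 * params.attack_blur_sigma
        )

    def split_for(i: int) -> str:
        if unknown_style:
            return "test_unknown"
        return "train" if i % 2 == 0 else "test_known"

    for i in range(n_real):
        img, gt = generate_eye(params, seed + i)
        images.append(img)
        truths.append(gt)
        records.append(
            DatasetRecord(
                path=f"synthetic/real_{i:04d}.png",
                label="bona_fide",
                split=split_for(i),
                subject_id=f"s{i:04d}",
            )
        )
    for i in range(n_attack):
        base_seed = seed + 100_000 + i
        img, gt = generate_eye(params, base_seed)
        img = make_attack(img, attack_params, base_seed + 500_000, gt=gt)
        images.append(img)
        truths.append(
            EyeGroundTruth(pupil=gt.pupil, iris=gt.iris, label="attack", seed=base_seed)
        )
        records.append(
            DatasetRecord(
                path=f"synthetic/attack_{i:04d}.png",
                label="attack",
                split=split_for(i),
                subject_id=f"a{i:04d}",
            )
        )
    return images, records, truths
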