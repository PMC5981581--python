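"""Image and dataset-manifest I/O plus deterministic training-set augmentation.

Grayscale eye images are represented throughout the package as 2-D
``numpy.ndarray`` of ``float64`` intensities in ``[0, 255]`` (row = y,
column = x).  Manifests are plain CSV files with the columns
``path,label,split,subject_id``; labels are serialized exactly as
``bona_fide`` / ``attack``.

Augmentation mirrors the common PAD training protocol of expanding each
bona-fide image into 14 extra variants and each attack image into 8 extra
variants by shifting, cropping and scaling, so that a training set of
``n_real`` + ``n_attack`` originals grows to ``15*n_real + 9*n_attack``
images with roughly balanced classes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

from irispad.errors import ValidationError

LABELS = ("bona_fide", "attack")
SPLITS = ("train", "test_known", "test_unknown")

#: anchors cycled for corner crops, in fixed order
_CROP_ANCHORS = ("tl", "tr", "bl", "br")


@dataclass(frozen=True)
class DatasetRecord:
    """One manifest row: an image path with its PAD label and split."""

    path: str
    label: str
    split: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.path:
            raise ValidationError("record path must be non-empty")
        if self.label not in LABELS:
            raise ValidationError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )
        if self.split not in SPLITS:
            raise ValidationError(
                f"unknown split {self.split!r}; expected one of {SPLITS}"
            )


@dataclass(frozen=True)
class AugmentationPlan:
    """Deterministic list of shift / crop / scale variants.

    ``n_variants`` equals the total number of listed transforms; every
    variant output has the same shape as its input (shifts are
    edge-padded, crops are rescaled back, scalings are center-cropped or
    edge-padded).
    """

    shift_offsets: tuple[tuple[int, int], ...] = ()
    crop_fractions: tuple[float, ...] = ()
    scale_factors: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for f in self.crop_fractions:
            if not 0.0 < f <= 1.0:
                raise ValidationError(f"crop fraction {f} outside (0, 1]")
        for s in self.scale_factors:
            if s <= 0:
                raise ValidationError(f"scale factor {s} must be positive")

    @property
    def n_variants(self) -> int:
        return (
            len(self.shift_offsets)
            + len(self.crop_fractions)
            + len(self.scale_factors)
        )


def _compass_shifts(magnitude: int = 5) -> tuple[tuple[int, int], ...]:
    m = magnitude
    return (
        (m, 0), (m, m), (0, m), (-m, m),
        (-m, 0), (-m, -m), (0, -m), (m, -m),
    )


#: 14 variants per bona-fide image: 8 compass shifts (±5 px), 4 corner
#: crops at fraction 0.9 rescaled to the original size, 2 scalings.
DEFAULT_BONA_FIDE_PLAN = AugmentationPlan(
    shift_offsets=_compass_shifts(5),
    crop_fractions=(0.9, 0.9, 0.9, 0.9),
    scale_factors=(0.95, 1.05),
)

#: 8 variants per attack image: the 8 compass shifts only.
DEFAULT_ATTACK_PLAN = AugmentationPlan(shift_offsets=_compass_shifts(5))

DEFAULT_PLANS = {"bona_fide": DEFAULT_BONA_FIDE_PLAN, "attack": DEFAULT_ATTACK_PLAN}


def load_gray(path: str | Path) -> np.ndarray:
    """Load an image file as a 2-D float64 grayscale array in [0, 255].

    Multi-channel inputs are converted to single-channel luminance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            gray = im.convert("L")
            arr = np.asarray(gray, dtype=np.float64)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable content
        raise ValidationError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"image {path} is not a non-empty 2-D raster")
    return arr


def save_gray(image: np.ndarray, path: str | Path) -> None:
    """Write a grayscale array as an 8-bit image (format from extension)."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0, 255)
    Image.fromarray(arr.round().astype(np.uint8), mode="L").save(path)


def read_manifest(path: str | Path) -> list[DatasetRecord]:
    """Read a CSV manifest with header ``path,label,split[,subject_id]``."""
    records: list[DatasetRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label", "split"} <= set(
            reader.fieldnames
        ):
            raise ValidationError(
                f"manifest {path} must have header columns path,label,split"
            )
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    DatasetRecord(
                        path=row["path"],
                        label=row["label"],
                        split=row["split"],
                        subject_id=row.get("subject_id") or "",
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


def write_manifest(records: list[DatasetRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split", "subject_id"])
        for r in records:
            writer.writerow([r.path, r.label, r.split, r.subject_id])


def _shift(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate by (dx, dy) pixels with edge replication."""
    h, w = image.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValidationError(
            f"shift ({dx},{dy}) magnitude exceeds image size {w}x{h}"
        )
    pad_y = (max(dy, 0), max(-dy, 0))
    pad_x = (max(dx, 0), max(-dx, 0))
    padded = np.pad(image, (pad_y, pad_x), mode="edge")
    y0 = max(-dy, 0)
    x0 = max(-dx, 0)
    return padded[y0 : y0 + h, x0 : x0 + w]


def _resize(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(
        image, shape, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )


def _crop(image: np.ndarray, fraction: float, anchor: str) -> np.ndarray:
    if fraction == 1.0:
        return image.copy()
    h, w = image.shape
    ch = max(1, int(round(h * fraction)))
    cw = max(1, int(round(w * fraction)))
    y0 = 0 if anchor in ("tl", "tr") else h - ch
    x0 = 0 if anchor in ("tl", "bl") else w - cw
    return _resize(image[y0 : y0 + ch, x0 : x0 + cw], (h, w))


def _scale(image: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return image.copy()
    h, w = image.shape
    sh = max(1, int(round(h * factor)))
    sw = max(1, int(round(w * factor)))
    scaled = _resize(image, (sh, sw))
    if factor > 1.0:  # center crop back to original
        y0 = (sh - h) // 2
        x0 = (sw - w) // 2
        return scaled[y0 : y0 + h, x0 : x0 + w]
    # pad back with edge replication, centered
    py = h - sh
    px = w - sw
    return np.pad(
        scaled,
        ((py // 2, py - py // 2), (px // 2, px - px // 2)),
        mode="edge",
    )


def augment(
    image: np.ndarray,
    label: str,
    plan: AugmentationPlan | None = None,
) -> list[np.ndarray]:
    """Produce the deterministic augmentation variants for one image.

    Under the default plans a bona-fide image yields 14 variants and an
    attack image 8.  Every output has the input's shape.
    """
    if plan is None:
        if label not in DEFAULT_PLANS:
            raise ValidationError(f"unknown label {label!r}")
        plan = DEFAULT_PLANS[label]
    image = np.asarray(image, dtype=np.float64)
    out: list[np.ndarray] = []
    for dx, dy in plan.shift_offsets:
        out.append(_shift(image, dx, dy))
    for j, frac in enumerate(plan.crop_fractions):
        out.append(_crop(image, frac, _CROP_ANCHORS[j % len(_CROP_ANCHORS)]))
    for factor in plan.scale_factors:
        out.append(_scale(image, factor))
    return out


def augmented_count(n_real: int, n_attack: int) -> int:
    """Total training images after augmentation (originals included).

    Each bona-fide original contributes 15 images (itself + 14 variants)
    and each attack original 9 (itself + 8 variants).
    """
    if n_real < 0 or n_attack < 0:
        raise ValidationError("counts must be non-negative")
    return n_real * 15 + n_attack * 9
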