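"""Multi-level uniform local-binary-pattern (LBP) histogram features.

An LBP operator with radius R and P sampling points encodes each pixel as

    LBP_{R,P} = sum_{i=0}^{P-1} s(g_i - g_c) * 2^i,   s(x) = 1 if x >= 0,

where g_c is the center intensity and g_i the bilinearly interpolated
intensity at angle 2*pi*i/P on the radius-R circle (i = 0 at angle 0,
proceeding counterclockwise).  Codes with at most two circular bitwise
transitions are *uniform* — they capture micro-texture such as edges,
corners, blobs and flat patches — and each gets its own histogram bin;
all remaining codes pool into a single non-uniform bin, which responds
strongly to the dot noise and broken texture of recaptured or printed
iris patterns.  The per-level histogram therefore has P*(P-1) + 3 bins.

The multi-level descriptor concatenates the histograms of seven (R, P)
levels — P=8 at R in {1,2,3}, and P=12 and P=16 at R in {2,3} (R=1 is
excluded for P >= 12, where the neighbor spacing would fall below one
pixel) — for a total of 3*59 + 2*135 + 2*243 = 933 dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from irispad._interp import bilinear
from irispad.errors import GeometryError, ValidationError


@dataclass(frozen=True)
class LBPConfig:
    """One LBP level: sampling radius R (px) and neighbor count P."""

    R: float
    P: int

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValidationError("R must be >= 1")
        if self.P < 4:
            raise ValidationError("P must be >= 4")

    @property
    def dim(self) -> int:
        return self.P * (self.P - 1) + 3


@dataclass(frozen=True)
class MLBPConfig:
    levels: tuple[LBPConfig, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValidationError("MLBP needs at least one level")

    @property
    def dim(self) -> int:
        return sum(level.dim for level in self.levels)


#: the seven-level default grid giving the 933-dimensional descriptor
DEFAULT_MLBP = MLBPConfig(
    levels=(
        LBPConfig(1, 8), LBPConfig(2, 8), LBPConfig(3, 8),
        LBPConfig(2, 12), LBPConfig(3, 12),
        LBPConfig(2, 16), LBPConfig(3, 16),
    )
)


@dataclass(frozen=True)
class FeatureVector:
    """Tagged 1-D descriptor (kind: mlbp | cnn | hybrid)."""

    values: np.ndarray
    kind: str

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


def lbp_code(center: float, neighbors) -> int:
    """Binary code of one neighborhood: bit i set iff g_i >= g_c."""
    code = 0
    for i, g in enumerate(neighbors):
        if g >= center:
            code |= 1 << i
    return code


def transition_count(code: int, P: int) -> int:
    """Number of circular adjacent bit changes, wrap-around included."""
    if code >= (1 << P):
        raise ValidationError(f"code {code} does not fit in {P} bits")
    rotated = ((code << 1) | (code >> (P - 1))) & ((1 << P) - 1)
    return bin(code ^ rotated).count("1")


def is_uniform(code: int, P: int) -> bool:
    return transition_count(code, P) <= 2


@lru_cache(maxsize=None)
def _bin_table(P: int) -> np.ndarray:
    """Map every P-bit code to its histogram bin.

    Uniform codes get bins 0..P(P-1)+1 ordered by code value; all
    non-uniform codes share the last bin, index P(P-1)+2.
    """
    codes = np.arange(1 << P, dtype=np.uint32)
    rotated = ((codes << 1) | (codes >> (P - 1))) & ((1 << P) - 1)
    diff = codes ^ rotated
    transitions = np.zeros(codes.shape, dtype=np.int64)
    for i in range(P):
        transitions += (diff >> i) & 1
    uniform = transitions <= 2
    table = np.full(1 << P, P * (P - 1) + 2, dtype=np.int64)
    table[uniform] = np.arange(int(uniform.sum()))
    return table


def _neighbor_offsets(config: LBPConfig) -> list[tuple[float, float]]:
    """(dx, dy) of sample i relative to the center, i = 0 at angle 0, CCW."""
    offs = []
    for i in range(config.P):
        ang = 2 * math.pi * i / config.P
        dx = config.R * math.cos(ang)
        dy = -config.R * math.sin(ang)
        # snap offsets that are integers up to trig rounding: keeps
        # lattice-aligned samples exact (no interpolation)
        if abs(dx - round(dx)) < 1e-9:
            dx = float(round(dx))
        if abs(dy - round(dy)) < 1e-9:
            dy = float(round(dy))
        offs.append((dx, dy))
    return offs


def sample_neighbors(
    image: np.ndarray, x: float, y: float, config: LBPConfig
) -> np.ndarray:
    """The P bilinearly interpolated neighbor intensities of one pixel."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if not (config.R <= x <= w - 1 - config.R and config.R <= y <= h - 1 - config.R):
        raise GeometryError(
            f"center ({x},{y}) closer than R={config.R} to the image border"
        )
    offs = _neighbor_offsets(config)
    xs = np.array([x + dx for dx, _ in offs])
    ys = np.array([y + dy for _, dy in offs])
    return bilinear(image, xs, ys)


def _neighbor_plane(
    image: np.ndarray, m: int, dx: float, dy: float
) -> np.ndarray:
    """Neighbor intensities at offset (dx, dy) for all interior centers.

    Interior centers are the pixels at least ``m`` from every border;
    because the offset is constant the bilinear weights are shared, so
    the whole plane is four shifted slices.
    """
    h, w = image.shape
    bx = int(math.floor(dx))
    by = int(math.floor(dy))
    fx = dx - bx
    fy = dy - by
    rows = slice(m + by, h - m + by)
    cols = slice(m + bx, w - m + bx)
    a = image[rows, cols]
    if fx > 0:
        cols1 = slice(m + bx + 1, w - m + bx + 1)
        top = a + fx * (image[rows, cols1] - a)
    else:
        top = a
    if fy == 0:
        return top
    rows1 = slice(m + by + 1, h - m + by + 1)
    c = image[rows1, cols]
    if fx > 0:
        bot = c + fx * (image[rows1, cols1] - c)
    else:
        bot = c
    return top + fy * (bot - top)


def lbp_histogram(
    image: np.ndarray, config: LBPConfig, normalize: bool = True
) -> FeatureVector:
    """Uniform-LBP histogram of one level, dimension P*(P-1)+3.

    Pixels within ceil(R) of the border are skipped (no padding); bins
    are L1-normalized by the number of encoded pixels.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    m = int(math.ceil(config.R))
    if h <= 2 * m or w <= 2 * m:
        raise GeometryError(f"image {w}x{h} too small for R={config.R}")
    gc = image[m : h - m, m : w - m]
    codes = np.zeros(gc.shape, dtype=np.int64)
    for i, (dx, dy) in enumerate(_neighbor_offsets(config)):
        gi = _neighbor_plane(image, m, dx, dy)
        codes |= (gi >= gc).astype(np.int64) << i
    bins = _bin_table(config.P)[codes]
    counts = np.bincount(bins.ravel(), minlength=config.dim).astype(np.float64)
    if normalize:
        counts /= gc.size
    return FeatureVector(values=counts, kind="mlbp")


def mlbp_features(
    image: np.ndarray, config: MLBPConfig = DEFAULT_MLBP
) -> FeatureVector:
    """Concatenated per-level histograms (933-d under the default grid).

    If a 3-channel ROI is passed, the first channel is used (the ROI
    channels are identical by construction).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = image[..., 0]
    parts = [lbp_histogram(image, level).values for level in config.levels]
    return FeatureVector(values=np.concatenate(parts), kind="mlbp")


def non_uniform_mass(features: FeatureVector, config: MLBPConfig = DEFAULT_MLBP) -> float:
    """Total normalized mass in the pooled non-uniform bins of all levels."""
    total = 0.0
    offset = 0
    for level in config.levels:
        total += float(features.values[offset + level.dim - 1])
        offset += level.dim
    return total
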