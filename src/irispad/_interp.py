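"""Bilinear interpolation shared by the circular samplers.

The two-stage form ``a + f*(b - a)`` is used deliberately: it is exactly
equivariant under adding a constant to the image, which makes the LBP
codes and the circular-edge objectives gray-shift invariant to the last
bit rather than merely to rounding error.
"""

from __future__ import annotations

import numpy as np


def bilinear(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Sample ``image`` at float coordinates (clamped to the border)."""
    h, w = image.shape
    x = np.clip(xs, 0.0, w - 1.0)
    y = np.clip(ys, 0.0, h - 1.0)
    x0 = np.floor(x).astype(np.intp)
    y0 = np.floor(y).astype(np.intp)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = x - x0
    fy = y - y0
    a = image[y0, x0]
    top = a + fx * (image[y0, x1] - a)
    c = image[y1, x0]
    bot = c + fx * (image[y1, x1] - c)
    return top + fy * (bot - top)
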