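"""Colour-distribution statistics of the lesion in five colour spaces.

RGB alone correlates strongly across channels and is not perceptually
uniform, so the catalogue also covers HSV, CIE L*a*b*, CIE L*u*v* and YCrCb.
Per the catalogue's published per-space feature counts, RGB and HSV emit four
*pooled* statistics over all in-mask channel values, while the three
perceptual spaces emit mean/std/skewness/kurtosis per channel (12 each),
for 4 + 4 + 12 + 12 + 12 = 44 colour features.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from skimage import color as skcolor

from ..errors import ValidationError

COLOR_SPACES = ("rgb", "hsv", "lab", "luv", "ycrcb")

_CHANNELS = {
    "lab": ("l", "a", "b"),
    "luv": ("l", "u", "v"),
    "ycrcb": ("y", "cr", "cb"),
}

_STATS = ("mean", "std", "skew", "kurt")


def _four_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, std, skewness, kurtosis); skew/kurt -> 0 when std == 0.

    The zero-variance check uses a relative tolerance: colour-space
    conversions leave ~1e-15 float noise on constant channels.
    """
    mean = float(values.mean())
    std = float(values.std())
    if std <= 1e-9 * max(1.0, abs(mean)):
        return mean, 0.0, 0.0, 0.0
    return mean, std, float(stats.skew(values)), float(stats.kurtosis(values))


def _convert(image: np.ndarray, space: str) -> np.ndarray:
    img = np.asarray(image, dtype=float) / 255.0
    if space == "rgb":
        return img * 255.0
    if space == "hsv":
        return skcolor.rgb2hsv(img)
    if space == "lab":
        return skcolor.rgb2lab(img)
    if space == "luv":
        return skcolor.rgb2luv(img)
    if space == "ycrcb":
        ycbcr = skcolor.rgb2ycbcr(img)
        return ycbcr[..., [0, 2, 1]]  # reorder to (Y, Cr, Cb)
    raise ValidationError(f"space: unknown colour space {space!r}")


def color_stats(image: np.ndarray, mask: np.ndarray, space: str) -> dict[str, float]:
    """Colour statistics for one space; see module docstring for counts."""
    space = space.lower()
    if space not in COLOR_SPACES:
        raise ValidationError(f"space: unknown colour space {space!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask: must be non-empty")
    converted = _convert(image, space)
    pixels = converted[mask]  # (n, 3)

    out: dict[str, float] = {}
    if space in ("rgb", "hsv"):
        pooled = pixels.ravel()
        for name, value in zip(_STATS, _four_stats(pooled)):
            key = "skewness" if name == "skew" else "kurtosis" if name == "kurt" else name
            out[f"{space}_{key}"] = value
    else:
        for c, channel in enumerate(_CHANNELS[space]):
            for name, value in zip(_STATS, _four_stats(pixels[:, c])):
                out[f"{space}_{name}_{channel}"] = value
    return out


def all_color_stats(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 44 colour features across the five spaces, in canonical order."""
    out: dict[str, float] = {}
    for space in COLOR_SPACES:
        out.update(color_stats(image, mask, space))
    return out
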