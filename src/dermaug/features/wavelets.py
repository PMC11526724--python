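"""Multiresolution texture: discrete wavelet transform and wavelet packets.

DWT: a 3-level ``bior3.3`` decomposition of the mean-filled lesion bounding
box; each detail subband (horizontal/vertical/diagonal per level) contributes
the mean and standard deviation of its absolute coefficients, plus the final
approximation band -- (3 levels x 3 bands + 1) x 2 = 20 features.

WP: a depth-3 ``coif1`` wavelet-packet decomposition; each of the 64 terminal
nodes (paths over {a, h, v, d}^3) contributes mean and std of absolute
coefficients -- 128 features.  Feature names follow the a/h/v/d path
convention, e.g. ``WP_coif1_aah_std``.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pywt

from ._util import filled_bbox

DWT_WAVELET = "bior3.3"
DWT_LEVELS = 3
WP_WAVELET = "coif1"
WP_DEPTH = 3

_DWT_BANDS = ("dh", "dv", "dd")  # horizontal, vertical, diagonal detail


def _stats(coeffs: np.ndarray) -> tuple[float, float]:
    a = np.abs(np.asarray(coeffs, dtype=float)).ravel()
    return float(a.mean()), float(a.std())


def dwt_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean/std of absolute coefficients per DWT subband (20 features)."""
    patch, _ = filled_bbox(image, mask, "DWT", min_side=2**DWT_LEVELS)
    coeffs = pywt.wavedec2(patch, DWT_WAVELET, level=DWT_LEVELS)
    out: dict[str, float] = {}
    approx = coeffs[0]
    mean, std = _stats(approx)
    out[f"DWT_{DWT_WAVELET}_l{DWT_LEVELS}_aa_mean"] = mean
    out[f"DWT_{DWT_WAVELET}_l{DWT_LEVELS}_aa_std"] = std
    # coeffs[1] is the deepest level; report levels 1..L from coarse to fine
    for idx, details in enumerate(coeffs[1:]):
        level = DWT_LEVELS - idx
        for band, arr in zip(_DWT_BANDS, details):
            mean, std = _stats(arr)
            out[f"DWT_{DWT_WAVELET}_l{level}_{band}_mean"] = mean
            out[f"DWT_{DWT_WAVELET}_l{level}_{band}_std"] = std
    return out


def wp_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean/std of absolute coefficients per depth-3 packet node (128 features)."""
    patch, _ = filled_bbox(image, mask, "WP", min_side=2**WP_DEPTH)
    wp = pywt.WaveletPacket2D(data=patch, wavelet=WP_WAVELET, maxlevel=WP_DEPTH)
    out: dict[str, float] = {}
    for path_tuple in product("ahvd", repeat=WP_DEPTH):
        path = "".join(path_tuple)
        mean, std = _stats(wp[path].data)
        out[f"WP_{WP_WAVELET}_{path}_mean"] = mean
        out[f"WP_{WP_WAVELET}_{path}_std"] = std
    return out
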