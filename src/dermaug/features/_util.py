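"""Shared helpers for the signal-processing texture families."""

from __future__ import annotations

import numpy as np

from ..errors import InsufficientSupportError
from ..preprocess import to_gray


def filled_bbox(image: np.ndarray, mask: np.ndarray, family: str,
                min_side: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Luma crop of the lesion bounding box with out-of-mask pixels filled by
    the in-mask mean; returns (patch, cropped_mask).

    The wavelet/spectral families operate on a rectangular support, so the
    surrounding skin is replaced by the lesion's mean gray level to avoid
    injecting background texture.  Raises the family's insufficient-support
    error when the bounding box is smaller than ``min_side`` on either side.
    """
    mask = np.asarray(mask, dtype=bool)
    gray = to_gray(image)
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    if (y1 - y0) < min_side or (x1 - x0) < min_side:
        raise InsufficientSupportError(
            f"insufficient-support: {family} needs a lesion bounding box of at "
            f"least {min_side}x{min_side} pixels"
        )
    patch = gray[y0:y1, x0:x1].copy()
    sub = mask[y0:y1, x0:x1]
    patch[~sub] = gray[mask].mean()
    return patch, sub
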