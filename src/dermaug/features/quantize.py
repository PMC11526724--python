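"""Shared front-end for the statistical texture families.

All gray-level-matrix families (co-occurrence, difference, run-length, size
zone, neighbourhood gray-tone difference) and the first-order statistics
operate on the same quantized representation: the ITU-R 601 luma image,
linearly rebinned to ``Ng`` levels over the min--max of in-mask pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from ..preprocess import to_gray


@dataclass
class GrayLesion:
    """Quantized in-mask gray levels.

    ``gray`` holds integer levels in [0, Ng-1]; values outside ``mask`` are
    present but flagged ignored -- every consumer restricts itself to in-mask
    pixels.
    """

    gray: np.ndarray
    mask: np.ndarray
    Ng: int

    def __post_init__(self):
        self.gray = np.asarray(self.gray)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.gray.shape != self.mask.shape:
            raise ValidationError("mask: shape must match gray image")
        if not self.mask.any():
            raise ValidationError("mask: must be non-empty")
        if self.gray[self.mask].max() >= self.Ng or self.gray[self.mask].min() < 0:
            raise ValidationError("gray: in-mask levels must lie in [0, Ng-1]")

    @property
    def levels(self) -> np.ndarray:
        """Flat array of in-mask levels."""
        return self.gray[self.mask]


def quantize_and_mask(image: np.ndarray, mask: np.ndarray, Ng: int = 32) -> GrayLesion:
    """Luma conversion + linear rebinning to ``Ng`` levels over the in-mask range.

    A constant in-mask region maps to level 0 everywhere (degenerate range).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask: must be non-empty")
    if Ng < 2:
        raise ValidationError("Ng: must be >= 2")
    gray = to_gray(image)
    lo = gray[mask].min()
    hi = gray[mask].max()
    if hi - lo < 1e-12:
        levels = np.zeros(gray.shape, dtype=np.int64)
    else:
        levels = np.floor((gray - lo) / (hi - lo) * Ng).astype(np.int64)
        levels = np.clip(levels, 0, Ng - 1)
    return GrayLesion(gray=levels, mask=mask, Ng=Ng)
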