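"""The full handcrafted feature catalogue: one lesion in, one named vector out.

``extract_all`` concatenates, in a fixed documented order,

1. the four geometric ABCD features,
2. 44 colour statistics over RGB / HSV / CIE L*a*b* / CIE L*u*v* / YCrCb,
3. twelve texture families: FOS, GLCM, GLDS, GLRLM, GLSZM, NGTDM_KING, SFM,
   LBP, HOS, FDTA, DWT, WP.

Column order is fixed by ``TEXTURE_FAMILIES`` and each family's internal
naming; two identical (image, mask) inputs produce identical vectors.
Degenerate inputs never yield NaN/inf -- each family maps its zero-variance
cases to documented constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DermaugError, InsufficientSupportError, ValidationError
from .abcd import abcd_features
from .color import all_color_stats
from .histogram import fos_features
from .local import lbp_features, sfm_features
from .matrices import (
    glcm_features,
    glds_features,
    glrlm_features,
    glszm_features,
    king_features,
)
from .quantize import GrayLesion, quantize_and_mask
from .spectral import fdta_features, hos_features
from .wavelets import dwt_features, wp_features

#: canonical family order of the catalogue
TEXTURE_FAMILIES = (
    "FOS", "GLCM", "GLDS", "GLRLM", "GLSZM", "NGTDM_KING",
    "SFM", "LBP", "HOS", "FDTA", "DWT", "WP",
)

#: families operating on the quantized GrayLesion
_QUANTIZED = {
    "FOS": fos_features,
    "GLCM": glcm_features,
    "GLDS": glds_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "NGTDM_KING": king_features,
}

#: families operating on the raw luma image + mask
_SPATIAL = {
    "SFM": sfm_features,
    "LBP": lbp_features,
    "HOS": hos_features,
    "FDTA": fdta_features,
    "DWT": dwt_features,
    "WP": wp_features,
}


@dataclass(frozen=True)
class ExtractionConfig:
    """Catalogue configuration: quantization depth and the families to run."""

    Ng: int = 32
    families: tuple[str, ...] = TEXTURE_FAMILIES
    include_abcd: bool = True
    include_color: bool = True

    def __post_init__(self):
        unknown = [f for f in self.families if f not in TEXTURE_FAMILIES]
        if unknown:
            raise ValidationError(f"families: unknown {unknown!r}")


def extract_texture_family(gl_or_image, family: str, mask: np.ndarray | None = None,
                           Ng: int = 32) -> dict[str, float]:
    """Named features of one texture family.

    Accepts either a pre-quantized :class:`GrayLesion` or an (image, mask)
    pair.  Raises :class:`ValidationError` for unknown families and the
    family-specific insufficient-support error for lesions below the family's
    minimum support.
    """
    if family not in TEXTURE_FAMILIES:
        raise ValidationError(f"family: unknown texture family {family!r}")
    if family in _QUANTIZED:
        gl = gl_or_image if isinstance(gl_or_image, GrayLesion) else \
            quantize_and_mask(gl_or_image, mask, Ng)
        return _QUANTIZED[family](gl)
    if isinstance(gl_or_image, GrayLesion):
        raise ValidationError(
            f"family: {family} operates on the raw image; pass (image, mask)")
    return _SPATIAL[family](gl_or_image, mask)


def extract_all(image: np.ndarray, mask: np.ndarray,
                config: ExtractionConfig | None = None) -> dict[str, float]:
    """The full catalogue for one lesion, as an ordered name -> value map."""
    config = config or ExtractionConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask: must be non-empty")
    out: dict[str, float] = {}
    if config.include_abcd:
        out.update(abcd_features(mask, image))
    if config.include_color:
        out.update(all_color_stats(image, mask))
    gl = quantize_and_mask(image, mask, config.Ng)
    for family in config.families:
        try:
            if family in _QUANTIZED:
                out.update(_QUANTIZED[family](gl))
            else:
                out.update(_SPATIAL[family](image, mask))
        except InsufficientSupportError:
            raise
        except DermaugError as exc:  # annotate with the failing family
            raise type(exc)(f"{family}: {exc}") from exc
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:  # contract: the catalogue never emits NaN/inf
        raise AssertionError(f"non-finite features produced: {bad[:5]}")
    return out


def catalogue_feature_names(config: ExtractionConfig | None = None) -> list[str]:
    """Fixed column order of the catalogue for the given configuration."""
    from ..simulate import SyntheticLesionSpec, generate_lesion_image

    sample = generate_lesion_image(SyntheticLesionSpec(
        image_size=64, texture_noise_sigma=5.0, variegation_spots=2, seed=0))
    return list(extract_all(sample.image, sample.mask, config).keys())
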