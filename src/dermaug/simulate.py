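"""Synthetic study material: lesion images and imbalanced feature tables.

Real dermoscopy collections are imbalanced (melanoma is the minority class)
and their images carry hair artifacts, irregular borders and variegated
pigment.  This module generates stand-ins with *known ground truth* for every
property the pipeline later tries to recover:

* :func:`generate_lesion_image` renders an elliptical lesion on a skin-toned
  background with independent knobs for the asymmetry (A), border
  irregularity (B), colour variegation (C) and diameter (D) of the clinical
  ABCD screening rule, plus optional dark hair strokes whose exact pixel
  footprint is returned for evaluating hair removal.
* :func:`generate_feature_table` draws an imbalanced two-class table with a
  known informative-feature block (class-conditional mean shift, within-block
  equicorrelation) padded with pure-noise features, for evaluating feature
  selection, oversampling and the statistical tests.
* :func:`toy_gray_matrix` is the tiny fixed gray-level matrix the texture
  operators are hand-verified against.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureTable, LesionSample
from .errors import ValidationError

SKIN_RGB = (224, 172, 138)  # constant beige background
HAIR_RGB = (38, 26, 20)

# Default palettes: light/dark browns for benign, darker + blue-gray for melanoma
BENIGN_PALETTE = [(150, 100, 70), (120, 75, 50)]
MELANOMA_PALETTE = [(90, 55, 40), (50, 30, 25), (98, 109, 126), (30, 20, 18)]


@dataclass(frozen=True)
class SyntheticLesionSpec:
    """Parameters of one rendered lesion.

    ``eccentricity`` is the major/minor semi-axis ratio (1 = circle);
    ``asymmetry_coeff`` in [0, 1] radially inflates one half of the lesion
    (0 = mirror-symmetric); ``border_waviness`` is a (amplitude px, frequency
    cycles) sinusoidal perturbation of the radius; ``texture_noise_sigma`` is
    in gray-level units.
    """

    image_size: int = 224
    eccentricity: float = 1.0
    asymmetry_coeff: float = 0.0
    border_waviness: tuple[float, float] = (0.0, 0.0)
    lesion_palette: tuple = ()
    variegation_spots: int = 0
    texture_noise_sigma: float = 0.0
    n_hairs: int = 0
    class_label: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValidationError("image_size: must be >= 64")
        if self.eccentricity < 1:
            raise ValidationError("eccentricity: must be >= 1")
        if not 0.0 <= self.asymmetry_coeff <= 1.0:
            raise ValidationError("asymmetry_coeff: must lie in [0, 1]")
        amp, freq = self.border_waviness
        if amp < 0 or freq < 0:
            raise ValidationError("border_waviness: amplitude/frequency must be >= 0")
        if self.variegation_spots < 0:
            raise ValidationError("variegation_spots: must be >= 0")
        if self.n_hairs < 0:
            raise ValidationError("n_hairs: must be >= 0")
        if self.texture_noise_sigma < 0:
            raise ValidationError("texture_noise_sigma: must be >= 0")
        if self.class_label not in (0, 1):
            raise ValidationError("class_label: must be 0 or 1")
        palette = self.lesion_palette or (
            MELANOMA_PALETTE if self.class_label == 1 else BENIGN_PALETTE
        )
        if len(palette) == 0:
            raise ValidationError("lesion_palette: must be non-empty")
        object.__setattr__(self, "lesion_palette", tuple(tuple(c) for c in palette))


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Parameters of one imbalanced feature table.

    ``effect_size`` is the class mean shift of each informative feature in
    units of its standard deviation; ``block_corr`` is the pairwise Pearson
    correlation within the informative block (equicorrelation model).
    """

    n_maj: int = 160
    n_min: int = 40
    n_features: int = 50
    n_informative: int = 10
    effect_size: float = 1.0
    block_corr: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_min > self.n_maj:
            raise ValidationError("n_min: must be <= n_maj")
        if self.n_min < 1 or self.n_maj < 1:
            raise ValidationError("n_min/n_maj: must be >= 1")
        if self.n_informative > self.n_features:
            raise ValidationError("n_informative: must be <= n_features")
        if not 0.0 <= self.block_corr < 1.0:
            raise ValidationError("block_corr: must lie in [0, 1)")


def _lesion_radius(theta: np.ndarray, spec: SyntheticLesionSpec, base_r: float,
                   phase: float) -> np.ndarray:
    """Polar radius of the lesion boundary at angles ``theta``."""
    ecc = spec.eccentricity
    a = base_r * np.sqrt(ecc)
    b = base_r / np.sqrt(ecc)
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    amp, freq = spec.border_waviness
    if amp > 0 and freq > 0:
        r = r + amp * np.sin(freq * theta + phase)
    if spec.asymmetry_coeff > 0:
        # one-sided radial scaling: inflate the upper half only
        r = r * (1.0 + spec.asymmetry_coeff * (np.sin(theta) > 0))
    return r


def _draw_hairs(image: np.ndarray, n_hairs: int, rng: np.random.Generator) -> np.ndarray:
    """Overlay dark anti-aliased quadratic Bezier strokes; return stroke mask."""
    size = image.shape[0]
    coverage = np.zeros(image.shape[:2], dtype=float)
    for _ in range(n_hairs):
        p0 = rng.uniform(0, size, size=2)
        p2 = rng.uniform(0, size, size=2)
        mid = (p0 + p2) / 2 + rng.uniform(-size / 4, size / 4, size=2)
        width = rng.uniform(0.5, 1.5)  # half-width -> 1-3 px strokes
        t = np.linspace(0, 1, 4 * size)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p2
        # splat each curve point into a local neighbourhood with a soft profile
        ys, xs = pts[:, 0], pts[:, 1]
        rad = int(np.ceil(width)) + 1
        for dy in range(-rad, rad + 1):
            for dx in range(-rad, rad + 1):
                yy = np.round(ys).astype(int) + dy
                xx = np.round(xs).astype(int) + dx
                ok = (yy >= 0) & (yy < size) & (xx >= 0) & (xx < size)
                d = np.hypot(yy - ys, xx - xs)[ok]
                alpha = np.clip(1.0 - (d - width), 0.0, 1.0)
                np.maximum.at(coverage, (yy[ok], xx[ok]), alpha)
    alpha = np.clip(coverage, 0, 1)
    alpha[alpha < 0.06] = 0.0  # keep the blended footprint == returned mask
    stroke_mask = alpha > 0
    hair = np.array(HAIR_RGB, dtype=float)
    image[:] = (1 - alpha[..., None]) * image + alpha[..., None] * hair
    return stroke_mask


def generate_lesion_image(spec: SyntheticLesionSpec) -> LesionSample:
    """Render one synthetic lesion; deterministic given ``spec`` (incl. seed).

    Returns a :class:`LesionSample` whose ``mask`` is the exact ground-truth
    lesion region and whose ``hair_mask`` (possibly empty) is the exact set of
    pixels touched by hair strokes.  The lesion-free rendering is unchanged by
    ``n_hairs``: hair uses an independent random substream, so the image with
    hairs differs from the hairless one only on stroke pixels.
    """
    base_ss, hair_ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(base_ss)
    size = spec.image_size

    cy, cx = size / 2 + rng.uniform(-2, 2, size=2)
    base_r = size * rng.uniform(0.24, 0.30)
    phase = rng.uniform(0, 2 * np.pi)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    mask = rho <= _lesion_radius(theta, spec, base_r, phase)

    from scipy.ndimage import gaussian_filter

    image = np.empty((size, size, 3), dtype=float)
    image[:] = SKIN_RGB
    skin_noise = gaussian_filter(rng.standard_normal((size, size)), sigma=1.0)
    image += (3.0 / skin_noise.std()) * skin_noise[..., None]  # skin micro-texture

    palette = np.array(spec.lesion_palette, dtype=float)
    image[mask] = palette[0]

    # colour variegation: palette-coloured blobs fully inside the lesion
    ys_in, xs_in = np.nonzero(mask)
    for _ in range(spec.variegation_spots):
        j = rng.integers(len(ys_in))
        sy, sx = ys_in[j], xs_in[j]
        colour = palette[rng.integers(1, len(palette))] if len(palette) > 1 else palette[0]
        srad = rng.uniform(0.14, 0.24) * base_r  # blobs, not hair-scale specks
        blob = (np.hypot(yy - sy, xx - sx) <= srad) & mask
        image[blob] = colour

    if spec.texture_noise_sigma > 0:
        # spatially correlated pigment texture (smoothed white noise, rescaled
        # to the requested per-pixel std) -- lesion texture, not sensor noise
        noise = gaussian_filter(rng.standard_normal((size, size)), sigma=2.5)
        noise *= spec.texture_noise_sigma / noise.std()
        image[mask] += noise[mask][:, None]

    hair_mask = np.zeros((size, size), dtype=bool)
    if spec.n_hairs > 0:
        hair_mask = _draw_hairs(image, spec.n_hairs, np.random.default_rng(hair_ss))

    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return LesionSample(
        image=image,
        mask=mask,
        label=spec.class_label,
        sample_id=f"synthetic_{spec.seed}",
        provenance={"generator": "simulate.generate_lesion_image", "seed": spec.seed},
        hair_mask=hair_mask,
    )


def generate_feature_table(spec: SyntheticTableSpec) -> tuple[FeatureTable, list[str]]:
    """Draw an imbalanced two-class table with a planted informative block.

    The first ``n_informative`` features are multivariate normal with unit
    variances, pairwise correlation ``block_corr`` and a between-class mean
    shift of ``effect_size`` standard deviations; the rest are standard-normal
    noise identical in distribution across classes.  Returns the table (all
    rows flagged as real) and the informative feature names.
    """
    rng = np.random.default_rng(spec.seed)
    D, k = spec.n_features, spec.n_informative
    n = spec.n_maj + spec.n_min
    y = np.concatenate([np.zeros(spec.n_maj, int), np.ones(spec.n_min, int)])

    X = rng.standard_normal((n, D))
    if k > 0:
        cov = np.full((k, k), spec.block_corr)
        np.fill_diagonal(cov, 1.0)
        L = np.linalg.cholesky(cov)
        X[:, :k] = X[:, :k] @ L.T
        X[y == 1, :k] += spec.effect_size

    names = [f"feat_{i:03d}" for i in range(D)]
    informative = names[:k]
    table = FeatureTable(pd.DataFrame(X, columns=names), y)
    return table, informative


#: Fixed 4x4, 4-gray-level matrix used by the brute-force texture oracles.
#: Rows (top to bottom): two flat 0/1 rows above a 2/3 block -- chosen so the
#: co-occurrence, difference, run-length and zone statistics all have short
#: hand-countable derivations.
_TOY = np.array(
    [
        [0, 0, 1, 1],
        [0, 0, 1, 1],
        [0, 2, 2, 2],
        [2, 2, 3, 3],
    ],
    dtype=np.int64,
)


def toy_gray_matrix() -> np.ndarray:
    """Return (a copy of) the fixed 4x4 oracle matrix with gray levels 0-3."""
    return _TOY.copy()
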