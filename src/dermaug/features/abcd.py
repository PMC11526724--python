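"""Geometric ABCD screening features of a lesion mask.

The clinical ABCD rule scores Asymmetry, Border irregularity, Colour count
and Diameter.  Here:

* ``geo_assymetry`` -- mean non-overlap fraction of the mask against its
  reflections across its two principal axes, in [0, 1] (0 = symmetric).
  The non-overlap fraction for one reflection is
  ``area(mask XOR reflected) / (2 * area(mask))``.
* ``geo_border`` -- compactness P^2 / (4 pi A), >= 1 up to discretisation
  (Crofton perimeter).
* ``geo_color`` -- number of reference dermoscopy colours (white, red, light
  brown, dark brown, blue-gray, black) occupying more than 1% of lesion
  pixels, pixels assigned by nearest RGB distance.
* ``geo_diameter`` -- maximum Feret diameter in pixels.

The spelling ``geo_assymetry`` is the catalogue's canonical (if unorthodox)
feature name and is kept for column-name stability.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from ..errors import ValidationError

#: reference dermoscopy colours, RGB
REFERENCE_COLORS = {
    "white": (255, 255, 255),
    "red": (204, 70, 70),
    "light_brown": (181, 134, 84),
    "dark_brown": (91, 59, 43),
    "blue_gray": (98, 109, 126),
    "black": (40, 30, 25),
}

ABCD_NAMES = ("geo_assymetry", "geo_border", "geo_color", "geo_diameter")


def _reflect_nonoverlap(mask: np.ndarray) -> float:
    """Mean symmetric-difference fraction across the two principal axes.

    Each principal axis passes through the mask centroid; the reflected mask
    is produced by a bilinear affine reflection of the mask image (thresholded
    at 0.5) to keep discretisation noise at the sub-pixel level.
    """
    ys, xs = np.nonzero(mask)
    pts = np.stack([ys, xs], axis=1).astype(float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    _, vecs = np.linalg.eigh(cov)  # columns: minor then major axis direction

    area = float(len(pts))
    mask_f = mask.astype(float)
    fracs = []
    for axis in (0, 1):
        u = vecs[:, axis]  # reflect across the line through centroid along u
        M = 2.0 * np.outer(u, u) - np.eye(2)
        offset = centroid - M @ centroid
        reflected = ndi.affine_transform(mask_f, M, offset=offset, order=1,
                                         mode="constant", cval=0.0) > 0.5
        sym_diff = float(np.logical_xor(mask, reflected).sum())
        fracs.append(sym_diff / (2.0 * area))
    return float(np.clip(np.mean(fracs), 0.0, 1.0))


def abcd_features(mask: np.ndarray, image: np.ndarray) -> dict[str, float]:
    """Compute the four geometric ABCD features; see module docstring."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask: must be non-empty")
    image = np.asarray(image)

    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(mask.sum())
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    border = perimeter**2 / (4.0 * np.pi * area) if area > 0 else 0.0

    rgb = image[mask].astype(float)
    refs = np.array(list(REFERENCE_COLORS.values()), dtype=float)
    d2 = ((rgb[:, None, :] - refs[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    occupancy = np.bincount(nearest, minlength=len(refs)) / len(rgb)
    n_colors = int((occupancy > 0.01).sum())

    return {
        "geo_assymetry": _reflect_nonoverlap(mask),
        "geo_border": float(border),
        "geo_color": float(n_colors),
        "geo_diameter": float(props.feret_diameter_max),
    }
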