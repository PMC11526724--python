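"""Lesion preprocessing: resizing, hair removal, fallback segmentation.

Dermoscopy images carry cutaneous artifacts -- hair above all -- that occlude
the texture, colour and boundary of the lesion.  The preprocessing stage
resizes every image to a common working size, detects thin dark curvilinear
structures with oriented morphological black-hat filtering, and replaces the
detected pixels by inpainting in fast-marching order (pixels filled from the
known boundary inward, nearest first).  Lesion masks are normally supplied
externally; :func:`segment_fallback` provides a classical threshold-based
segmenter so the synthetic pipeline runs end to end without one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, transform
from skimage.filters import threshold_otsu

from .errors import SegmentationEmptyError, ValidationError

#: ITU-R 601 luma weights, the fixed grayscale convention of the package
LUMA_601 = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class PreprocessConfig:
    """Hair-removal and resizing parameters.

    Black-hat structuring elements are lines of ``blackhat_kernel_lengths``
    pixels at each of ``blackhat_orientations`` degrees; responses above
    ``hair_threshold`` gray levels (union over all elements) form the hair
    mask, which is inpainted with neighbourhood radius ``inpaint_radius``.
    """

    target_size: int = 224
    blackhat_kernel_lengths: tuple[int, ...] = (9, 15)
    blackhat_orientations: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    hair_threshold: float = 20.0
    inpaint_radius: int = 3

    def __post_init__(self):
        if self.target_size <= 0:
            raise ValidationError("target_size: must be > 0")
        if any(l < 3 for l in self.blackhat_kernel_lengths):
            raise ValidationError("blackhat_kernel_lengths: lengths must be >= 3")
        if any(not 0 <= o < 180 for o in self.blackhat_orientations):
            raise ValidationError("blackhat_orientations: must lie in [0, 180)")


def to_gray(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma in [0, 255] as float."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    r, g, b = LUMA_601
    return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]


def resize_image(image: np.ndarray, target_size: int = 224) -> np.ndarray:
    """Resample to ``target_size`` x ``target_size`` by direct resampling.

    RGB images are resampled bilinearly with anti-aliasing; boolean masks use
    nearest-neighbour so they stay binary.  No padding: aspect ratio is not
    preserved.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValidationError("image: empty input")
    if img.ndim == 2:
        if img.dtype == bool:
            out = transform.resize(
                img.astype(float), (target_size, target_size), order=0,
                anti_aliasing=False, preserve_range=True,
            )
            return out > 0.5
        out = transform.resize(img, (target_size, target_size),
                               anti_aliasing=True, preserve_range=True)
        return out.astype(img.dtype) if np.issubdtype(img.dtype, np.integer) else out
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError("image: expected (H, W) or (H, W, 3) array")
    out = transform.resize(img, (target_size, target_size, 3),
                           anti_aliasing=True, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Binary line structuring element of ``length`` px at ``angle_deg``."""
    theta = np.deg2rad(angle_deg)
    half = (length - 1) / 2
    t = np.arange(-half, half + 0.5)
    ys = np.round(t * np.sin(theta)).astype(int)
    xs = np.round(t * np.cos(theta)).astype(int)
    fp = np.zeros((2 * int(np.max(np.abs(ys), initial=0)) + 1,
                   2 * int(np.max(np.abs(xs), initial=0)) + 1), dtype=bool)
    fp[ys + fp.shape[0] // 2, xs + fp.shape[1] // 2] = True
    return fp


def detect_hair(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Hair mask: union over orientations/lengths of thresholded black-hat."""
    config = config or PreprocessConfig()
    gray = to_gray(image)
    mask = np.zeros(gray.shape, dtype=bool)
    for length in config.blackhat_kernel_lengths:
        for angle in config.blackhat_orientations:
            fp = _line_footprint(length, angle)
            response = morphology.closing(gray, fp) - gray
            mask |= response > config.hair_threshold
    return mask


def inpaint_fast_marching(image: np.ndarray, mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Fill ``mask`` pixels in fast-marching order from the known boundary.

    Unknown pixels are processed in increasing distance from the nearest known
    pixel (the order a fast-marching front would reach them) and each is set
    to the inverse-distance-weighted mean of already-known values within
    ``radius``.  Pixels outside the mask are returned unchanged.
    """
    orig = np.asarray(image)
    was_2d = orig.ndim == 2
    img = np.atleast_3d(np.asarray(orig, dtype=float).copy())
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return orig.copy()
    dist = ndi.distance_transform_edt(mask)
    order = np.argsort(dist[mask], kind="stable")
    ys, xs = np.nonzero(mask)
    ys, xs = ys[order], xs[order]
    known_orig = ~mask  # preferring true pixels keeps edges from smearing
    known = ~mask
    h, w = mask.shape
    offsets = [
        (dy, dx, 1.0 / np.hypot(dy, dx))
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if (dy, dx) != (0, 0) and dy * dy + dx * dx <= radius * radius
    ]
    for y, x in zip(ys, xs):
        acc = np.zeros(img.shape[2])
        wsum = 0.0
        for use in (known_orig, known):
            for dy, dx, wgt in offsets:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and use[ny, nx]:
                    acc += wgt * img[ny, nx]
                    wsum += wgt
            if wsum > 0:
                break  # fall back to filled neighbours only when necessary
        if wsum > 0:
            img[y, x] = acc / wsum
        known[y, x] = True
    out = img[..., 0] if was_2d else img
    if np.issubdtype(orig.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(orig.dtype)
    return out


def remove_hair(image: np.ndarray, config: PreprocessConfig | None = None,
                n_passes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Detect hair strokes and inpaint them; returns (clean_image, hair_mask).

    Detection and filling are iterated ``n_passes`` times (filled streaks can
    leave faint residues at lesion-edge crossings that a refinement pass
    cleans up); the returned hair mask is the union over passes, and pixels
    outside it are bit-identical to the input.
    """
    config = config or PreprocessConfig()
    clean = image
    union = np.zeros(np.asarray(image).shape[:2], dtype=bool)
    for _ in range(max(1, n_passes)):
        hair = detect_hair(clean, config)
        if not hair.any():
            break
        union |= hair
        clean = inpaint_fast_marching(clean, hair, radius=config.inpaint_radius)
    return clean, union


def segment_fallback(image: np.ndarray) -> np.ndarray:
    """Classical lesion segmentation: Otsu threshold on the luma image, keep
    the largest dark connected component, fill holes.

    Intended only for synthetic fixtures and smoke runs -- real masks should
    come from a dedicated segmenter.  Raises :class:`SegmentationEmptyError`
    when no foreground component exists (e.g. a constant image).
    """
    gray = to_gray(image)
    if np.ptp(gray) < 1e-9:
        raise SegmentationEmptyError("segmentation-empty: constant image")
    thr = threshold_otsu(gray)
    fg = gray < thr  # lesion darker than surrounding skin
    if not fg.any():
        raise SegmentationEmptyError("segmentation-empty: no dark foreground")
    labels, n = ndi.label(fg)
    if n == 0:
        raise SegmentationEmptyError("segmentation-empty: no connected component")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    mask = ndi.binary_fill_holes(labels == keep)
    return mask
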