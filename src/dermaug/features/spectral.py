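"""Higher-order spectral and fractal texture features.

HOS: the lesion patch is projected onto a line (Radon transform) at a fixed
angle; the third-order spectrum (bispectrum) of the 1-D projection is
accumulated directly as B(f1, f2) = X(f1) X(f2) conj(X(f1 + f2)) over the
principal region, and the feature is the normalized entropy of the bispectral
phase distribution -- a measure of the non-Gaussian phase coupling in the
texture.  One feature per configured angle.

FDTA: multiresolution fractal texture.  At four dyadic resolutions (the patch
block-averaged by 1, 2, 4, 8) a Hurst-type roughness exponent is estimated
from the scaling of mean absolute intensity differences with lag,
E|g(p) - g(p+d)| ~ d^H, via a log-log fit over d in {1, 2, 4}.  Constant
patches map to H = 0 by convention.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import radon

from ._util import filled_bbox

HOS_ANGLES = (135.0, 140.0)
_N_PHASE_BINS = 32


def _bispectrum_phase_entropy(signal: np.ndarray, n_bins: int = _N_PHASE_BINS) -> float:
    """Normalized entropy of the bispectral phase over the principal region."""
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0):
        return 0.0
    X = np.fft.fft(x)
    n = len(X)
    half = n // 2
    # principal region: 0 <= f2 <= f1, f1 + f2 < n/2
    f1 = np.arange(half)[:, None]
    f2 = np.arange(half)[None, :]
    region = (f2 <= f1) & (f1 + f2 < half)
    B = X[f1] * X[f2] * np.conj(X[(f1 + f2) % n])
    phases = np.angle(B[region])
    mags = np.abs(B[region])
    if mags.sum() <= 0:
        return 0.0
    hist, _ = np.histogram(phases, bins=n_bins, range=(-np.pi, np.pi), weights=mags)
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(n_bins))


def hos_features(image: np.ndarray, mask: np.ndarray,
                 angles: tuple[float, ...] = HOS_ANGLES) -> dict[str, float]:
    """Bispectral phase entropy of the Radon projection at each angle."""
    patch, _ = filled_bbox(image, mask, "HOS", min_side=8)
    patch = patch - patch[~np.isnan(patch)].mean()
    out = {}
    for angle in angles:
        projection = radon(patch, theta=[angle], circle=False)[:, 0]
        name = f"HOS_{int(angle)}_degrees"
        out[name] = _bispectrum_phase_entropy(projection)
    return out


def _block_mean(patch: np.ndarray, factor: int) -> np.ndarray:
    h, w = (patch.shape[0] // factor) * factor, (patch.shape[1] // factor) * factor
    if h == 0 or w == 0:
        return patch
    trimmed = patch[:h, :w]
    return trimmed.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def _hurst(patch: np.ndarray, lags=(1, 2, 4)) -> float:
    diffs = []
    used = []
    for d in lags:
        if patch.shape[0] <= d or patch.shape[1] <= d:
            continue
        dh = np.abs(patch[:, d:] - patch[:, :-d]).mean()
        dv = np.abs(patch[d:, :] - patch[:-d, :]).mean()
        md = (dh + dv) / 2.0
        if md > 0:
            diffs.append(md)
            used.append(d)
    if len(diffs) < 2:
        return 0.0  # constant (or too small) patch
    slope = np.polyfit(np.log(used), np.log(diffs), 1)[0]
    return float(slope)


def fdta_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Four Hurst coefficients at dyadic resolutions 1, 1/2, 1/4, 1/8."""
    patch, _ = filled_bbox(image, mask, "FDTA", min_side=16)
    out = {}
    for k in range(4):
        reduced = _block_mean(patch, 2**k)
        out[f"FDTA_HurstCoeff_{k + 1}"] = _hurst(reduced)
    return out
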