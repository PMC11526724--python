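"""First-order statistics (FOS) of the in-mask gray-level histogram."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .quantize import GrayLesion

FOS_NAMES = (
    "fos_energy", "fos_mean", "fos_std", "fos_median", "fos_variance",
    "fos_mode", "fos_skew", "fos_entropy", "fos_mngl", "fos_mxgl",
    "fos_cov", "fos_10", "fos_25", "fos_75", "fos_90",
)


def fos_features(gl: GrayLesion) -> dict[str, float]:
    """15 statistics of the quantized in-mask gray distribution.

    Zero-variance convention: skewness and the coefficient of variation are 0
    when the in-mask standard deviation is 0.
    """
    v = gl.levels.astype(float)
    hist = np.bincount(gl.levels, minlength=gl.Ng).astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]
    mean = float(v.mean())
    std = float(v.std())
    out = {
        "fos_energy": float((p**2).sum()),
        "fos_mean": mean,
        "fos_std": std,
        "fos_median": float(np.median(v)),
        "fos_variance": float(v.var()),
        "fos_mode": float(np.argmax(hist)),
        "fos_skew": float(stats.skew(v)) if std > 0 else 0.0,
        "fos_entropy": float(-(nz * np.log2(nz)).sum()),
        "fos_mngl": float(v.min()),
        "fos_mxgl": float(v.max()),
        "fos_cov": std / mean if (std > 0 and mean != 0) else 0.0,
        "fos_10": float(np.percentile(v, 10)),
        "fos_25": float(np.percentile(v, 25)),
        "fos_75": float(np.percentile(v, 75)),
        "fos_90": float(np.percentile(v, 90)),
    }
    return out
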