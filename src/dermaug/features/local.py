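"""Local texture codes: local binary patterns and the statistical feature matrix."""

from __future__ import annotations

import numpy as np
from skimage.feature import local_binary_pattern

from ..errors import InsufficientSupportError
from ._util import filled_bbox

#: (radius, points) configurations of the LBP block
LBP_CONFIGS = ((1, 8), (2, 16), (3, 24))


def _hist_energy_entropy(codes: np.ndarray, n_bins: int) -> tuple[float, float]:
    hist = np.bincount(codes.astype(int), minlength=n_bins).astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]
    return float((p**2).sum()), float(-(nz * np.log2(nz)).sum())


def lbp_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Energy and entropy of uniform-LBP histograms at three (R, P) scales.

    Codes are computed on the mean-filled lesion bounding box; histograms are
    restricted to in-mask pixels.  Emits 6 features.
    """
    patch, sub = filled_bbox(image, mask, "LBP", min_side=8)
    patch = np.round(patch).astype(np.int64)  # LBP comparisons want integer levels
    out: dict[str, float] = {}
    for radius, points in LBP_CONFIGS:
        codes = local_binary_pattern(patch, P=points, R=radius, method="uniform")
        energy, entropy = _hist_energy_entropy(codes[sub], n_bins=points + 2)
        out[f"LBP_R_{radius}_P_{points}_energy"] = energy
        out[f"LBP_R_{radius}_P_{points}_entropy"] = entropy
    return out


def sfm_features(image: np.ndarray, mask: np.ndarray, max_lag: int = 4) -> dict[str, float]:
    """Statistical-feature-matrix texture measures.

    Over displacements (dy, dx) with 0 <= dy <= L, |dx| <= L (L = ``max_lag``),
    the dissimilarity DSS(dy,dx) = E|g(p) - g(p + (dy,dx))| and contrast
    CON(dy,dx) = E[(g(p) - g(p + (dy,dx)))^2] are estimated over in-mask pairs.

    * coarseness  = n_displacements / sum(DSS)        (flat image -> capped 1e6)
    * contrast    = sqrt((CON(0,1) + CON(1,0)) / 4)
    * periodicity = (mean(DSS) - min(DSS)) / mean(DSS)
    * roughness   = mean log-log slope-based fractal estimate of DSS growth
                    along the axes: (3 - H) averaged over rows/cols, where H is
                    the Hurst-type exponent of DSS(d) ~ d^H for d = 1..L.
    """
    patch, sub = filled_bbox(image, mask, "SFM", min_side=max_lag + 2)
    h, w = patch.shape
    dss: dict[tuple[int, int], float] = {}
    con: dict[tuple[int, int], float] = {}
    for dy in range(0, max_lag + 1):
        for dx in range(-max_lag, max_lag + 1):
            if dy == 0 and dx <= 0:
                continue
            ay = slice(max(0, -dy), h - max(0, dy))
            ax = slice(max(0, -dx), w - max(0, dx))
            by = slice(max(0, dy), h + min(0, dy))
            bx = slice(max(0, dx), w + min(0, dx))
            valid = sub[ay, ax] & sub[by, bx]
            if not valid.any():
                continue
            diff = patch[ay, ax][valid] - patch[by, bx][valid]
            dss[(dy, dx)] = float(np.abs(diff).mean())
            con[(dy, dx)] = float((diff**2).mean())
    if not dss:
        raise InsufficientSupportError("insufficient-support: SFM needs >= 2 in-mask pixel pairs")

    dss_vals = np.array(list(dss.values()))
    total = dss_vals.sum()
    coarseness = min(len(dss_vals) / total, 1e6) if total > 0 else 1e6
    contrast = float(np.sqrt((con.get((0, 1), 0.0) + con.get((1, 0), 0.0)) / 4.0))
    mean_dss = dss_vals.mean()
    periodicity = float((mean_dss - dss_vals.min()) / mean_dss) if mean_dss > 0 else 0.0

    hursts = []
    for axis_lags in ([(0, d) for d in range(1, max_lag + 1)],
                      [(d, 0) for d in range(1, max_lag + 1)]):
        d_valid = [(np.hypot(*lag), dss[lag]) for lag in axis_lags
                   if lag in dss and dss[lag] > 0]
        if len(d_valid) >= 2:
            logs = np.log([d for d, _ in d_valid])
            vals = np.log([v for _, v in d_valid])
            hursts.append(np.polyfit(logs, vals, 1)[0])
    roughness = float(np.mean([3.0 - hh for hh in hursts])) if hursts else 3.0

    return {
        "SFM_Coarseness": float(coarseness),
        "SFM_Contrast": contrast,
        "SFM_Periodicity": periodicity,
        "SFM_Roughness": roughness,
    }
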