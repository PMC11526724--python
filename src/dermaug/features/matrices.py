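"""Gray-level matrix texture families: GLCM, GLDS, GLRLM, GLSZM, NGTDM.

All five families reduce the quantized lesion to a counting matrix and emit
named statistics of it.  Conventions shared across the module:

* only pixels inside the lesion mask participate; a pixel pair / run / zone
  is counted only if *every* pixel involved is in-mask;
* directional families (co-occurrence, difference statistics, run lengths)
  are computed at distance 1 in the four offsets (0,1), (1,0), (1,1), (1,-1)
  and averaged, which makes them invariant to 90-degree rotations;
* entropies use base-2 logarithms;
* gray levels are indexed 1-based (level + 1) inside weighting formulas so
  that low-gray-level emphasis terms are well defined;
* zero-variance degenerate cases map to 0 rather than NaN, except NGTDM
  coarseness which is capped at 1e6 for a perfectly flat lesion.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from ..errors import InsufficientSupportError, NoPairsError
from .quantize import GrayLesion

OFFSETS_4 = ((0, 1), (1, 0), (1, 1), (1, -1))

_EPS = np.finfo(float).tiny


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _pair_views(g: np.ndarray, m: np.ndarray, dy: int, dx: int):
    """Aligned views (a, b, valid) of all pixel pairs (p, p + (dy, dx))."""
    h, w = g.shape
    ay = slice(max(0, -dy), h - max(0, dy))
    ax = slice(max(0, -dx), w - max(0, dx))
    by = slice(max(0, dy), h + min(0, dy))
    bx = slice(max(0, dx), w + min(0, dx))
    a, b = g[ay, ax], g[by, bx]
    valid = m[ay, ax] & m[by, bx]
    return a, b, valid


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def cooccurrence_matrix(gl: GrayLesion, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one displacement.

    A pair is counted (in both directions) only when both pixels lie in-mask.
    Raises :class:`NoPairsError` when the displacement yields no valid pair.
    """
    dy, dx = offset
    if (dy, dx) == (0, 0):
        raise NoPairsError("offset must be non-zero")
    g, m, Ng = gl.gray, gl.mask, gl.Ng
    a, b, valid = _pair_views(g, m, dy, dx)
    if not valid.any():
        raise NoPairsError(f"no in-mask pixel pairs at offset {offset}")
    i = a[valid].ravel()
    j = b[valid].ravel()
    P = np.zeros((Ng, Ng), dtype=float)
    np.add.at(P, (i, j), 1.0)
    np.add.at(P, (j, i), 1.0)  # symmetric: count both directions
    return P / P.sum()


def haralick_features(P: np.ndarray) -> dict[str, float]:
    """The 14 Haralick statistics of one normalized co-occurrence matrix."""
    Ng = P.shape[0]
    i = np.arange(Ng)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 0..2Ng-2 and p_{x-y}(k), k = 0..Ng-1
    p_sum = np.zeros(2 * Ng - 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2 * Ng - 1)
    k_diff = np.arange(Ng)

    asm = float((P**2).sum())
    contrast = float((k_diff**2 * p_diff).sum())
    if sd_x > 0 and sd_y > 0:
        corr = float(((ii - mu_x) * (jj - mu_y) * P).sum() / (sd_x * sd_y))
    else:
        corr = 0.0
    sos = float(((ii - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sa = float((k_sum * p_sum).sum())
    sv = float(((k_sum - sa) ** 2 * p_sum).sum())
    se = _entropy2(p_sum)
    ent = _entropy2(P.ravel())
    dmu = float((k_diff * p_diff).sum())
    dv = float(((k_diff - dmu) ** 2 * p_diff).sum())
    de = _entropy2(p_diff)

    # information measures of correlation
    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy = np.outer(px, py)
    nz = (P > 0)
    hxy1 = float(-(P[nz] * np.log2(pxy[nz] + _EPS)).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    denom = max(hx, hy)
    imc1 = (ent - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))

    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    keep = (px > 0) & (py > 0)
    if keep.sum() >= 2:
        Pk = P[np.ix_(keep, keep)]
        Q = (Pk / px[keep][:, None]) @ (Pk / py[keep][:, None]).T
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2].real))) if len(eig) >= 2 else 0.0
    else:
        mcc = 0.0

    return {
        "glcm_asm": asm,
        "glcm_contrast": contrast,
        "glcm_corr": corr,
        "glcm_sos": sos,
        "glcm_idm": idm,
        "glcm_sa": sa,
        "glcm_sv": sv,
        "glcm_se": se,
        "glcm_entropy": ent,
        "glcm_dv": dv,
        "glcm_de": de,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_mcc": mcc,
    }


def glcm_features(gl: GrayLesion) -> dict[str, float]:
    """14 Haralick statistics averaged over the four distance-1 offsets."""
    per_offset = []
    for off in OFFSETS_4:
        try:
            per_offset.append(haralick_features(cooccurrence_matrix(gl, off)))
        except NoPairsError:
            continue
    if not per_offset:
        raise InsufficientSupportError("insufficient-support: GLCM needs >= 2 in-mask pixel pairs")
    return {k: float(np.mean([d[k] for d in per_offset])) for k in per_offset[0]}


# ---------------------------------------------------------------------------
# GLDS
# ---------------------------------------------------------------------------

def gray_level_difference_histogram(gl: GrayLesion, offset: tuple[int, int]) -> np.ndarray:
    """Normalized histogram of |level difference| for one displacement."""
    dy, dx = offset
    g, m, Ng = gl.gray, gl.mask, gl.Ng
    a, b, valid = _pair_views(g, m, dy, dx)
    if not valid.any():
        raise NoPairsError(f"no in-mask pixel pairs at offset {offset}")
    diffs = np.abs(a[valid].astype(int) - b[valid].astype(int))
    hist = np.bincount(diffs, minlength=Ng).astype(float)
    return hist / hist.sum()


def glds_features(gl: GrayLesion) -> dict[str, float]:
    """The canonical five difference statistics, 4-direction average."""
    hists = []
    for off in OFFSETS_4:
        try:
            hists.append(gray_level_difference_histogram(gl, off))
        except NoPairsError:
            continue
    if not hists:
        raise InsufficientSupportError("insufficient-support: GLDS needs >= 2 in-mask pixel pairs")
    d = np.arange(gl.Ng)
    vals = {"glds_H": [], "glds_C": [], "glds_energy": [], "glds_entropy": [], "glds_M": []}
    for p in hists:
        vals["glds_H"].append(float((p / (1.0 + d**2)).sum()))
        vals["glds_C"].append(float((d**2 * p).sum()))
        vals["glds_energy"].append(float((p**2).sum()))
        vals["glds_entropy"].append(_entropy2(p))
        vals["glds_M"].append(float((d * p).sum()))
    return {k: float(np.mean(v)) for k, v in vals.items()}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _lines(g: np.ndarray, m: np.ndarray, direction: tuple[int, int]):
    """Yield (levels, mask) 1-D traversals of the image along a direction."""
    h, w = g.shape
    if direction == (0, 1):
        for y in range(h):
            yield g[y], m[y]
    elif direction == (1, 0):
        for x in range(w):
            yield g[:, x], m[:, x]
    elif direction == (1, 1):
        for off in range(-h + 1, w):
            yield g.diagonal(off), m.diagonal(off)
    elif direction == (1, -1):
        gf, mf = g[:, ::-1], m[:, ::-1]
        for off in range(-h + 1, w):
            yield gf.diagonal(off), mf.diagonal(off)
    else:  # pragma: no cover - internal contract
        raise ValueError(f"unsupported run direction {direction}")


def run_length_matrix(gl: GrayLesion, direction: tuple[int, int]) -> np.ndarray:
    """Run-length matrix P[level, run_length - 1] for one direction.

    A run is a maximal sequence of consecutive equal-level in-mask pixels
    along the direction; out-of-mask pixels break runs.
    """
    g, m, Ng = gl.gray, gl.mask, gl.Ng
    h, w = g.shape
    P = np.zeros((Ng, max(h, w)), dtype=float)
    for line_g, line_m in _lines(g, m, direction):
        if not line_m.any():
            continue
        n = len(line_g)
        # a run breaks when the mask flag or the level changes
        key = np.where(line_m, line_g.astype(np.int64), -1)
        breaks = np.flatnonzero(np.diff(key) != 0)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [n]])
        for s0, e0 in zip(starts, ends):
            if line_m[s0]:
                P[line_g[s0], e0 - s0 - 1] += 1.0
    return P


def _glrlm_stats(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    Nr = P.sum()
    if Nr == 0:
        raise InsufficientSupportError("insufficient-support: GLRLM found no runs")
    i = np.arange(1, P.shape[0] + 1, dtype=float)  # 1-based gray level
    j = np.arange(1, P.shape[1] + 1, dtype=float)  # run length
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = P / Nr
    r_i = P.sum(axis=1)  # runs per gray level
    r_j = P.sum(axis=0)  # runs per length
    mu_i = float((i * r_i).sum() / Nr)
    mu_j = float((j * r_j).sum() / Nr)
    return {
        "glrlm_sre": float((P / jj**2).sum() / Nr),
        "glrlm_lre": float((P * jj**2).sum() / Nr),
        "glrlm_gln": float((r_i**2).sum() / Nr),
        "glrlm_glnn": float((r_i**2).sum() / Nr**2),
        "glrlm_rln": float((r_j**2).sum() / Nr),
        "glrlm_rlnn": float((r_j**2).sum() / Nr**2),
        "glrlm_rp": float(Nr / n_pixels),
        "glrlm_glv": float((p * (ii - mu_i) ** 2).sum()),
        "glrlm_rlv": float((p * (jj - mu_j) ** 2).sum()),
        "glrlm_re": _entropy2(p.ravel()),
        "glrlm_lglre": float((P / ii**2).sum() / Nr),
        "glrlm_hglre": float((P * ii**2).sum() / Nr),
        "glrlm_srlgle": float((P / (ii**2 * jj**2)).sum() / Nr),
        "glrlm_srhgle": float((P * ii**2 / jj**2).sum() / Nr),
        "glrlm_lrlgle": float((P * jj**2 / ii**2).sum() / Nr),
        "glrlm_lrhgle": float((P * ii**2 * jj**2).sum() / Nr),
    }


def glrlm_features(gl: GrayLesion) -> dict[str, float]:
    """16 run-length statistics, averaged over the four directions."""
    n_pixels = int(gl.mask.sum())
    per_dir = [_glrlm_stats(run_length_matrix(gl, d), n_pixels) for d in OFFSETS_4]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def size_zone_matrix(gl: GrayLesion) -> np.ndarray:
    """Size-zone matrix P[level, size - 1]; zones are 8-connected components
    of equal gray level within the mask."""
    g, m, Ng = gl.gray, gl.mask, gl.Ng
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    max_size = int(m.sum())
    P = np.zeros((Ng, max_size), dtype=float)
    for level in range(Ng):
        region = (g == level) & m
        if not region.any():
            continue
        labels, n = ndi.label(region, structure=structure)
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        for s in sizes.astype(int):
            P[level, s - 1] += 1.0
    return P


def glszm_features(gl: GrayLesion) -> dict[str, float]:
    """The 14 zone statistics."""
    P = size_zone_matrix(gl)
    Nz = P.sum()
    if Nz == 0:
        raise InsufficientSupportError("insufficient-support: GLSZM found no zones")
    n_pixels = int(gl.mask.sum())
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    s = np.arange(1, P.shape[1] + 1, dtype=float)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    p = P / Nz
    z_i = P.sum(axis=1)
    z_s = P.sum(axis=0)
    mu_i = float((i * z_i).sum() / Nz)
    mu_s = float((s * z_s).sum() / Nz)
    return {
        "glszm_sze": float((P / ss**2).sum() / Nz),
        "glszm_lze": float((P * ss**2).sum() / Nz),
        "glszm_glnu": float((z_i**2).sum() / Nz),
        "glszm_zsnu": float((z_s**2).sum() / Nz),
        "glszm_lglze": float((P / ii**2).sum() / Nz),
        "glszm_zp": float(Nz / n_pixels),
        "glszm_hglze": float((P * ii**2).sum() / Nz),
        "glszm_szlgle": float((P / (ii**2 * ss**2)).sum() / Nz),
        "glszm_szhgle": float((P * ii**2 / ss**2).sum() / Nz),
        "glszm_lzlgle": float((P * ss**2 / ii**2).sum() / Nz),
        "glszm_lzhgle": float((P * ii**2 * ss**2).sum() / Nz),
        "glszm_glvar": float((p * (ii - mu_i) ** 2).sum()),
        "glszm_zsvar": float((p * (ss - mu_s) ** 2).sum()),
        "glszm_zsentr": _entropy2(p.ravel()),
    }


# ---------------------------------------------------------------------------
# NGTDM (Amadasun & King)
# ---------------------------------------------------------------------------

def ngtdm_table(gl: GrayLesion) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i): per-level pixel counts and summed gray-tone differences.

    For each in-mask pixel with at least one in-mask 8-neighbour, the
    gray-tone difference is |level - mean(neighbour levels)|.
    """
    g, m, Ng = gl.gray.astype(float), gl.mask, gl.Ng
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    neigh_sum = ndi.convolve(np.where(m, g, 0.0), kernel, mode="constant")
    neigh_cnt = ndi.convolve(m.astype(float), kernel, mode="constant")
    valid = m & (neigh_cnt > 0)
    n_i = np.zeros(Ng)
    s_i = np.zeros(Ng)
    levels = gl.gray[valid]
    diffs = np.abs(g[valid] - neigh_sum[valid] / neigh_cnt[valid])
    np.add.at(n_i, levels, 1.0)
    np.add.at(s_i, levels, diffs)
    return n_i, s_i


def king_features(gl: GrayLesion) -> dict[str, float]:
    """NGTDM coarseness, contrast, busyness, complexity, strength."""
    n_i, s_i = ngtdm_table(gl)
    N = n_i.sum()
    if N == 0:
        raise InsufficientSupportError("insufficient-support: NGTDM_KING needs neighboured pixels")
    p = n_i / N
    i = np.arange(len(p), dtype=float) + 1.0
    nz = p > 0
    Ngp = int(nz.sum())

    coars_den = float((p * s_i).sum())
    coarseness = min(1.0 / coars_den, 1e6) if coars_den > 0 else 1e6

    if Ngp > 1:
        pij = np.outer(p[nz], p[nz])
        dij2 = (i[nz][:, None] - i[nz][None, :]) ** 2
        contrast = float((pij * dij2).sum() / (Ngp * (Ngp - 1)) * (s_i.sum() / N))
    else:
        contrast = 0.0

    busy_den = float(np.abs(i[nz][:, None] * p[nz][:, None]
                            - i[nz][None, :] * p[nz][None, :]).sum())
    busyness = float((p * s_i).sum() / busy_den) if busy_den > 0 else 0.0

    if Ngp > 1:
        ia, pa, sa = i[nz][:, None], p[nz][:, None], s_i[nz][:, None]
        ib, pb, sb = i[nz][None, :], p[nz][None, :], s_i[nz][None, :]
        complexity = float((np.abs(ia - ib) * (pa * sa + pb * sb) / (pa + pb)).sum() / N)
        strength_num = float(((pa + pb) * (ia - ib) ** 2).sum())
    else:
        complexity = 0.0
        strength_num = 0.0
    s_total = float(s_i.sum())
    strength = strength_num / s_total if s_total > 0 else 0.0

    return {
        "king_coarseness": float(coarseness),
        "king_contrast": contrast,
        "king_busyness": busyness,
        "king_complexity": complexity,
        "king_strength": strength,
    }
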