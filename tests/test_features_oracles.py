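"""Texture families against independent brute-force oracles on the 4x4 fixture.

Every oracle below is a naive double/triple loop written directly from the
textbook definition, independent of the package's vectorised implementations.
Matrix-counting families (GLCM, GLDS, GLRLM, GLSZM, NGTDM) must agree exactly;
derived statistics to 1e-9.
"""

import numpy as np
import pytest

from dermaug import toy_gray_matrix
from dermaug.errors import NoPairsError, ValidationError
from dermaug.features import (
    GrayLesion,
    cooccurrence_matrix,
    fos_features,
    glcm_features,
    glds_features,
    glrlm_features,
    glszm_features,
    gray_level_difference_histogram,
    haralick_features,
    king_features,
    ngtdm_table,
    quantize_and_mask,
    run_length_matrix,
    size_zone_matrix,
)

OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _full_gl(matrix, Ng=4):
    return GrayLesion(gray=np.asarray(matrix), mask=np.ones_like(matrix, bool), Ng=Ng)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_glcm(g, m, dy, dx, Ng):
    """Double-loop symmetric pair count."""
    P = np.zeros((Ng, Ng))
    h, w = g.shape
    for y in range(h):
        for x in range(w):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and m[y, x] and m[ny, nx]:
                P[g[y, x], g[ny, nx]] += 1
                P[g[ny, nx], g[y, x]] += 1
    return P / P.sum()


def brute_glds_hist(g, m, dy, dx, Ng):
    counts = np.zeros(Ng)
    h, w = g.shape
    for y in range(h):
        for x in range(w):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and m[y, x] and m[ny, nx]:
                counts[abs(int(g[y, x]) - int(g[ny, nx]))] += 1
    return counts / counts.sum()


def brute_runs(g, m, dy, dx):
    """Walk every line of the image, recording (level, run_length) pairs."""
    h, w = g.shape
    runs = []
    seen = np.zeros_like(m, dtype=bool)
    for y0 in range(h):
        for x0 in range(w):
            py, px = y0 - dy, x0 - dx
            inside_prev = 0 <= py < h and 0 <= px < w
            if not m[y0, x0]:
                continue
            if inside_prev and m[py, px] and g[py, px] == g[y0, x0]:
                continue  # not a run start
            level, length = g[y0, x0], 0
            y, x = y0, x0
            while 0 <= y < h and 0 <= x < w and m[y, x] and g[y, x] == level:
                length += 1
                seen[y, x] = True
                y, x = y + dy, x + dx
            runs.append((int(level), length))
    return runs


def brute_zones(g, m, Ng):
    """Flood-fill (8-connected) zones of equal level; returns (level, size)."""
    h, w = g.shape
    visited = np.zeros_like(m, dtype=bool)
    zones = []
    for y0 in range(h):
        for x0 in range(w):
            if not m[y0, x0] or visited[y0, x0]:
                continue
            level = g[y0, x0]
            stack, size = [(y0, x0)], 0
            visited[y0, x0] = True
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and m[ny, nx] \
                                and not visited[ny, nx] and g[ny, nx] == level:
                            visited[ny, nx] = True
                            stack.append((ny, nx))
            zones.append((int(level), size))
    return zones


def brute_ngtdm(g, m, Ng):
    h, w = g.shape
    n_i = np.zeros(Ng)
    s_i = np.zeros(Ng)
    for y in range(h):
        for x in range(w):
            if not m[y, x]:
                continue
            neigh = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dy, dx) == (0, 0):
                        continue
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and m[ny, nx]:
                        neigh.append(float(g[ny, nx]))
            if not neigh:
                continue
            n_i[g[y, x]] += 1
            s_i[g[y, x]] += abs(float(g[y, x]) - np.mean(neigh))
    return n_i, s_i


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestCooccurrence:
    def test_matches_literal_hand_count(self, toy_gl):
        """GLCM(0,1) of the fixture equals the hand count of horizontal
        adjacent pairs: (0,0)x2, (0,1)x2, (1,1)x2, (0,2)x1, (2,2)x3,
        (2,3)x1, (3,3)x1 -- doubled for symmetry, normalized by 24."""
        P = cooccurrence_matrix(toy_gl, (0, 1))
        hand = np.zeros((4, 4))
        for (i, j), c in {(0, 0): 2, (0, 1): 2, (1, 1): 2, (0, 2): 1,
                          (2, 2): 3, (2, 3): 1, (3, 3): 1}.items():
            hand[i, j] += c
            hand[j, i] += c
        assert np.allclose(P, hand / hand.sum())

    @pytest.mark.parametrize("offset", OFFSETS)
    def test_matches_brute_force_all_offsets(self, toy_gl, offset):
        P = cooccurrence_matrix(toy_gl, offset)
        B = brute_glcm(toy_gl.gray, toy_gl.mask, *offset, toy_gl.Ng)
        assert np.allclose(P, B)

    def test_constant_image_single_diagonal_entry(self):
        gl = _full_gl(np.zeros((4, 4), dtype=int))
        P = cooccurrence_matrix(gl, (0, 1))
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_symmetric_and_normalized(self, textured_gl):
        P = cooccurrence_matrix(textured_gl, (1, 1))
        assert np.array_equal(P, P.T)
        assert abs(P.sum() - 1.0) < 1e-12

    def test_masked_pairs_excluded(self):
        toy = toy_gray_matrix()
        mask = np.ones_like(toy, bool)
        mask[:, 2:] = False  # only the left 4x2 block
        gl = GrayLesion(gray=toy, mask=mask, Ng=4)
        P = cooccurrence_matrix(gl, (0, 1))
        assert np.allclose(P, brute_glcm(toy, mask, 0, 1, 4))

    def test_zero_offset_and_no_pairs_errors(self, toy_gl):
        with pytest.raises(NoPairsError):
            cooccurrence_matrix(toy_gl, (0, 0))
        single = GrayLesion(gray=np.zeros((3, 3), int),
                            mask=np.eye(3, dtype=bool), Ng=4)
        with pytest.raises(NoPairsError):
            cooccurrence_matrix(single, (0, 1))


class TestHaralick:
    def test_statistics_match_textbook_formulas_on_own_matrix(self, toy_gl):
        """Each Haralick value equals a brute-force evaluation of its formula
        on the op's own co-occurrence matrix."""
        P = cooccurrence_matrix(toy_gl, (0, 1))
        feats = haralick_features(P)
        Ng = P.shape[0]
        mu_x = sum(i * P[i, j] for i in range(Ng) for j in range(Ng))
        mu_y = sum(j * P[i, j] for i in range(Ng) for j in range(Ng))
        sd_x = np.sqrt(sum((i - mu_x) ** 2 * P[i, j]
                           for i in range(Ng) for j in range(Ng)))
        asm = sum(P[i, j] ** 2 for i in range(Ng) for j in range(Ng))
        contrast = sum((i - j) ** 2 * P[i, j]
                       for i in range(Ng) for j in range(Ng))
        idm = sum(P[i, j] / (1 + (i - j) ** 2)
                  for i in range(Ng) for j in range(Ng))
        ent = -sum(P[i, j] * np.log2(P[i, j])
                   for i in range(Ng) for j in range(Ng) if P[i, j] > 0)
        sa = sum((i + j) * P[i, j] for i in range(Ng) for j in range(Ng))
        corr = sum((i - mu_x) * (j - mu_y) * P[i, j]
                   for i in range(Ng) for j in range(Ng)) / sd_x**2  # sd_x=sd_y
        assert feats["glcm_asm"] == pytest.approx(asm, abs=1e-12)
        assert feats["glcm_contrast"] == pytest.approx(contrast, abs=1e-12)
        assert feats["glcm_idm"] == pytest.approx(idm, abs=1e-12)
        assert feats["glcm_entropy"] == pytest.approx(ent, abs=1e-12)
        assert feats["glcm_sa"] == pytest.approx(sa, abs=1e-12)
        assert feats["glcm_corr"] == pytest.approx(corr, abs=1e-12)

    def test_constant_lesion_degenerate_values(self):
        gl = _full_gl(np.zeros((6, 6), dtype=int))
        feats = glcm_features(gl)
        assert feats["glcm_contrast"] == 0.0
        assert feats["glcm_entropy"] == 0.0
        assert feats["glcm_asm"] == 1.0
        assert feats["glcm_corr"] == 0.0  # zero-variance convention


class TestGLDS:
    @pytest.mark.parametrize("offset", OFFSETS)
    def test_histogram_matches_brute_force(self, toy_gl, offset):
        h = gray_level_difference_histogram(toy_gl, offset)
        assert np.allclose(h, brute_glds_hist(toy_gl.gray, toy_gl.mask,
                                              *offset, toy_gl.Ng))

    def test_statistics_from_own_histogram(self, toy_gl):
        feats = glds_features(toy_gl)
        per_offset = [brute_glds_hist(toy_gl.gray, toy_gl.mask, dy, dx, 4)
                      for dy, dx in OFFSETS]
        d = np.arange(4)
        assert feats["glds_C"] == pytest.approx(
            np.mean([(d**2 * p).sum() for p in per_offset]), abs=1e-12)
        assert feats["glds_M"] == pytest.approx(
            np.mean([(d * p).sum() for p in per_offset]), abs=1e-12)
        assert feats["glds_H"] == pytest.approx(
            np.mean([(p / (1 + d**2)).sum() for p in per_offset]), abs=1e-12)

    def test_constant_lesion_zero_contrast(self):
        feats = glds_features(_full_gl(np.full((5, 5), 2, dtype=int)))
        assert feats["glds_C"] == 0.0
        assert feats["glds_H"] == 1.0


class TestGLRLM:
    def test_constant_rows_single_run_each(self):
        """A constant 4x4 matrix has one length-4 run per row horizontally."""
        g = np.full((4, 4), 1, dtype=int)
        P = run_length_matrix(_full_gl(g), (0, 1))
        expected = np.zeros((4, 4))
        expected[1, 3] = 4  # level 1, run length 4, four rows
        assert np.array_equal(P, expected)

    @pytest.mark.parametrize("direction", OFFSETS)
    def test_matrix_matches_brute_walk(self, toy_gl, direction):
        P = run_length_matrix(toy_gl, direction)
        runs = brute_runs(toy_gl.gray, toy_gl.mask, *direction)
        B = np.zeros_like(P)
        for level, length in runs:
            B[level, length - 1] += 1
        assert np.array_equal(P, B)

    @pytest.mark.parametrize("direction", OFFSETS)
    def test_matrix_matches_brute_walk_textured(self, textured_gl, direction):
        """Same agreement on a real 224x224 lesion (crops to keep it quick)."""
        g = textured_gl.gray[60:110, 60:110]
        m = textured_gl.mask[60:110, 60:110]
        gl = GrayLesion(gray=g, mask=m, Ng=textured_gl.Ng)
        P = run_length_matrix(gl, direction)
        runs = brute_runs(g, m, *direction)
        B = np.zeros_like(P)
        for level, length in runs:
            B[level, length - 1] += 1
        assert np.array_equal(P, B)

    def test_statistics_against_direct_formulas(self, toy_gl):
        feats = glrlm_features(toy_gl)
        # recompute one direction set by hand and average
        vals = {k: [] for k in ("sre", "rp", "gln")}
        n_pix = int(toy_gl.mask.sum())
        for direction in OFFSETS:
            runs = brute_runs(toy_gl.gray, toy_gl.mask, *direction)
            Nr = len(runs)
            vals["sre"].append(np.mean([0]) + sum(1 / l**2 for _, l in runs) / Nr)
            vals["rp"].append(Nr / n_pix)
            per_level = np.zeros(4)
            for lev, _ in runs:
                per_level[lev] += 1
            vals["gln"].append((per_level**2).sum() / Nr)
        assert feats["glrlm_sre"] == pytest.approx(np.mean(vals["sre"]), abs=1e-12)
        assert feats["glrlm_rp"] == pytest.approx(np.mean(vals["rp"]), abs=1e-12)
        assert feats["glrlm_gln"] == pytest.approx(np.mean(vals["gln"]), abs=1e-12)


class TestGLSZM:
    def test_zone_matrix_matches_flood_fill(self, toy_gl):
        P = size_zone_matrix(toy_gl)
        zones = brute_zones(toy_gl.gray, toy_gl.mask, toy_gl.Ng)
        B = np.zeros_like(P)
        for level, size in zones:
            B[level, size - 1] += 1
        assert np.array_equal(P, B)

    def test_fixture_zones_are_the_hand_enumeration(self, toy_gl):
        """The fixture has exactly 4 zones: 0s (5 px), 1s (4 px), 2s (5 px),
        3s (2 px) -- all 8-connected."""
        zones = sorted(brute_zones(toy_gl.gray, toy_gl.mask, 4))
        assert zones == [(0, 5), (1, 4), (2, 5), (3, 2)]
        feats = glszm_features(toy_gl)
        assert feats["glszm_zp"] == pytest.approx(4 / 16)
        assert feats["glszm_glnu"] == pytest.approx((1 + 1 + 1 + 1) / 4)

    def test_statistics_against_direct_formulas(self, textured_gl):
        g = textured_gl.gray[60:100, 60:100]
        m = textured_gl.mask[60:100, 60:100]
        gl = GrayLesion(gray=g, mask=m, Ng=textured_gl.Ng)
        feats = glszm_features(gl)
        zones = brute_zones(g, m, gl.Ng)
        Nz = len(zones)
        sze = sum(1 / s**2 for _, s in zones) / Nz
        lze = sum(s**2 for _, s in zones) / Nz
        assert feats["glszm_sze"] == pytest.approx(sze, rel=1e-12)
        assert feats["glszm_lze"] == pytest.approx(lze, rel=1e-12)


class TestNGTDM:
    def test_table_matches_brute_force(self, toy_gl):
        n_i, s_i = ngtdm_table(toy_gl)
        bn, bs = brute_ngtdm(toy_gl.gray, toy_gl.mask, toy_gl.Ng)
        assert np.allclose(n_i, bn)
        assert np.allclose(s_i, bs)

    def test_table_matches_brute_force_masked(self, textured_gl):
        g = textured_gl.gray[80:110, 80:110]
        m = textured_gl.mask[80:110, 80:110]
        gl = GrayLesion(gray=g, mask=m, Ng=textured_gl.Ng)
        n_i, s_i = ngtdm_table(gl)
        bn, bs = brute_ngtdm(g, m, gl.Ng)
        assert np.allclose(n_i, bn)
        assert np.allclose(s_i, bs)

    def test_flat_lesion_conventions(self):
        feats = king_features(_full_gl(np.zeros((5, 5), int)))
        assert feats["king_coarseness"] == 1e6  # capped, not infinite
        assert feats["king_contrast"] == 0.0
        assert feats["king_busyness"] == 0.0


class TestRotationInvariance:
    @pytest.mark.parametrize("family", [glcm_features, glds_features,
                                        glrlm_features, glszm_features,
                                        king_features])
    def test_four_direction_families_invariant_under_90_degrees(
            self, textured_gl, family):
        gl = textured_gl
        rotated = GrayLesion(gray=np.rot90(gl.gray).copy(),
                             mask=np.rot90(gl.mask).copy(), Ng=gl.Ng)
        a = family(gl)
        b = family(rotated)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9), key


class TestQuantize:
    def test_constant_region_maps_to_level_zero(self):
        img = np.full((8, 8, 3), 77, dtype=np.uint8)
        gl = quantize_and_mask(img, np.ones((8, 8), bool), Ng=32)
        assert (gl.levels == 0).all()

    def test_extremes_map_to_extremes(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0] = 10
        img[1] = 200
        gl = quantize_and_mask(img, np.ones((2, 2), bool), Ng=32)
        assert set(gl.levels) == {0, 31}

    def test_identity_rebinning_on_fixture(self):
        toy = toy_gray_matrix()
        img = np.stack([toy * 85] * 3, axis=-1).astype(np.uint8)
        gl = quantize_and_mask(img, np.ones_like(toy, bool), Ng=4)
        assert np.array_equal(gl.gray, toy)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError, match="mask"):
            quantize_and_mask(np.zeros((4, 4, 3)), np.zeros((4, 4), bool))


class TestFOS:
    def test_emits_exactly_15_statistics(self, toy_gl):
        assert len(fos_features(toy_gl)) == 15

    def test_values_against_direct_computation(self, toy_gl):
        feats = fos_features(toy_gl)
        v = toy_gl.gray[toy_gl.mask].astype(float)
        assert feats["fos_mean"] == pytest.approx(v.mean())
        assert feats["fos_std"] == pytest.approx(v.std())
        assert feats["fos_median"] == pytest.approx(np.median(v))
        assert feats["fos_90"] == pytest.approx(np.percentile(v, 90))
        hist = np.bincount(v.astype(int), minlength=4) / len(v)
        assert feats["fos_energy"] == pytest.approx((hist**2).sum())

    def test_constant_lesion_degenerates_to_zero(self):
        feats = fos_features(_full_gl(np.zeros((5, 5), int)))
        assert feats["fos_std"] == 0.0
        assert feats["fos_skew"] == 0.0
        assert feats["fos_cov"] == 0.0
        assert feats["fos_entropy"] == 0.0
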