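"""Texture feature formulas on GLCM, GLRLM, GLSZM and NGTDM.

All features are computed on normalized matrices in COO form.  Degenerate
cases (single gray level, single cell) are detected and returned in a
separate set so the robustness stage can exclude them pairwise instead of
propagating NaN.

Feature rosters per family (40 features total):
GLCM (9):  energy, contrast, correlation, homogeneity, entropy,
           dissimilarity, variance, cluster shade, cluster prominence
GLRLM (13): SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE,
           LRHGE, GLV, RLV
GLSZM (13): SAE, LAE, GLN, ZSN, ZP, LGZE, HGZE, SALGE, SAHGE, LALGE,
           LAHGE, GLV, ZSV
NGTDM (5): coarseness, contrast, busyness, complexity, strength
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrixSet

__all__ = [
    "texture_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "TEXTURE_NAMES",
]

GLCM_NAMES = (
    "glcm_energy", "glcm_contrast", "glcm_correlation", "glcm_homogeneity",
    "glcm_entropy", "glcm_dissimilarity", "glcm_variance",
    "glcm_cluster_shade", "glcm_cluster_prominence",
)
GLRLM_NAMES = (
    "glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp",
    "glrlm_lgre", "glrlm_hgre", "glrlm_srlge", "glrlm_srhge",
    "glrlm_lrlge", "glrlm_lrhge", "glrlm_glv", "glrlm_rlv",
)
GLSZM_NAMES = (
    "glszm_sae", "glszm_lae", "glszm_gln", "glszm_zsn", "glszm_zp",
    "glszm_lgze", "glszm_hgze", "glszm_salge", "glszm_sahge",
    "glszm_lalge", "glszm_lahge", "glszm_glv", "glszm_zsv",
)
NGTDM_NAMES = (
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
    "ngtdm_complexity", "ngtdm_strength",
)
TEXTURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES


def _glcm_features(m: TextureMatrixSet, out: dict, degenerate: set) -> None:
    i = m.glcm_i.astype(float)
    j = m.glcm_j.astype(float)
    tot = m.glcm_c.sum()
    if tot == 0:  # single voxel: no neighbor pairs at all
        for name in GLCM_NAMES:
            out[name] = 0.0
            degenerate.add(name)
        return
    p = m.glcm_c / tot
    out["glcm_energy"] = float((p**2).sum())
    out["glcm_contrast"] = float((p * (i - j) ** 2).sum())
    out["glcm_dissimilarity"] = float((p * np.abs(i - j)).sum())
    out["glcm_homogeneity"] = float((p / (1.0 + np.abs(i - j))).sum())
    out["glcm_entropy"] = float(-(p * np.log2(p)).sum())
    mu = float((p * i).sum())  # symmetric: row mean == column mean
    var = float((p * (i - mu) ** 2).sum())
    out["glcm_variance"] = var
    if var > 0:
        out["glcm_correlation"] = float(((p * i * j).sum() - mu * mu) / var)
    else:
        out["glcm_correlation"] = 0.0
        degenerate.add("glcm_correlation")
    s = i + j - 2 * mu
    out["glcm_cluster_shade"] = float((p * s**3).sum())
    out["glcm_cluster_prominence"] = float((p * s**4).sum())


def _rl_features(g, r, c, n_voxels, names, out, degenerate, n_dirs=1) -> None:
    """Shared run-length / size-zone formulas; ``r`` is length or zone size.

    ``n_dirs`` divides the run/zone percentage so that a matrix merged
    over 13 directions still yields RP = 1 when every run has length 1.
    """
    nr = c.sum()
    if nr == 0:
        for name in names:
            out[name] = 0.0
            degenerate.add(name)
        return
    g = g.astype(float)
    r = r.astype(float)
    p = c / nr
    sre, lre, gln, rln, rp = names[0], names[1], names[2], names[3], names[4]
    out[sre] = float((p / r**2).sum())
    out[lre] = float((p * r**2).sum())
    out[rln] = _marginal_nonuniformity(r, c, nr)
    out[gln] = _marginal_nonuniformity(g, c, nr)
    out[rp] = float(nr / (n_voxels * n_dirs))
    out[names[5]] = float((p / g**2).sum())          # LGRE / LGZE
    out[names[6]] = float((p * g**2).sum())          # HGRE / HGZE
    out[names[7]] = float((p / (g**2 * r**2)).sum())  # SRLGE / SALGE
    out[names[8]] = float((p * g**2 / r**2).sum())   # SRHGE / SAHGE
    out[names[9]] = float((p * r**2 / g**2).sum())   # LRLGE / LALGE
    out[names[10]] = float((p * g**2 * r**2).sum())  # LRHGE / LAHGE
    mu_g = float((p * g).sum())
    out[names[11]] = float((p * (g - mu_g) ** 2).sum())  # GLV
    mu_r = float((p * r).sum())
    out[names[12]] = float((p * (r - mu_r) ** 2).sum())  # RLV / ZSV
    if c.size == 1:
        for name in names:
            degenerate.add(name)


def _marginal_nonuniformity(keys, counts, total) -> float:
    uniq, inv = np.unique(keys, return_inverse=True)
    sums = np.bincount(inv, weights=counts)
    return float((sums**2).sum() / total)


def _ngtdm_features(m: TextureMatrixSet, out: dict, degenerate: set) -> None:
    lv = m.ngtdm_levels.astype(float)
    n_i = m.ngtdm_n
    s_i = m.ngtdm_s
    N = n_i.sum()
    if N == 0:
        for name in NGTDM_NAMES:
            out[name] = 0.0
            degenerate.add(name)
        return
    p = n_i / N
    ps = float((p * s_i).sum())
    ngp = lv.size
    out["ngtdm_coarseness"] = float(1.0 / ps) if ps > 0 else 1e6
    if ps == 0:
        degenerate.add("ngtdm_coarseness")
    # pairwise sums over occupied levels; separable closed forms keep the
    # cost O(G) even for fixed-bin-width level counts in the thousands
    mu = float((p * lv).sum())
    var = float((p * (lv - mu) ** 2).sum())
    if ngp > 1:
        out["ngtdm_contrast"] = float(2.0 * var / (ngp * (ngp - 1)) * s_i.sum() / N)
    else:
        out["ngtdm_contrast"] = 0.0
        degenerate.add("ngtdm_contrast")
    denom = _pairwise_absdiff_sum(lv * p)
    if denom > 0:
        out["ngtdm_busyness"] = float(ps / denom)
    else:
        out["ngtdm_busyness"] = 0.0
        degenerate.add("ngtdm_busyness")
    out["ngtdm_complexity"] = _ngtdm_complexity(lv, p, s_i) / N
    ssum = s_i.sum()
    if ssum > 0:
        # sum_ij (p_i + p_j)(i-j)^2 = 2 * sum_i p_i * sum_j (i-j)^2
        sj = lv.sum()
        sj2 = (lv**2).sum()
        inner = ngp * lv**2 - 2 * lv * sj + sj2
        out["ngtdm_strength"] = float(2.0 * (p * inner).sum() / ssum)
    else:
        out["ngtdm_strength"] = 0.0
        degenerate.add("ngtdm_strength")


def _pairwise_absdiff_sum(a: np.ndarray) -> float:
    """sum_ij |a_i - a_j| in O(n log n) via the sorted prefix identity."""
    s = np.sort(a)
    n = s.size
    k = np.arange(n)
    return float(2.0 * (s * (2 * k + 1 - n)).sum())


def _ngtdm_complexity(lv, p, s_i, chunk: int = 256) -> float:
    """sum_ij |i-j| (p_i s_i + p_j s_j) / (p_i + p_j), chunked over rows."""
    total = 0.0
    ps = p * s_i
    for start in range(0, lv.size, chunk):
        sl = slice(start, start + chunk)
        absd = np.abs(lv[sl, None] - lv[None, :])
        num = ps[sl, None] + ps[None, :]
        total += float((absd * num / (p[sl, None] + p[None, :])).sum())
    return total


def texture_features(m: TextureMatrixSet) -> tuple[dict[str, float], set[str]]:
    """All 40 texture features of one matrix set.

    Returns (values, degenerate names).  A single-gray-level volume yields
    valid run/zone statistics but degenerate co-occurrence correlation and
    gray-tone contrast; those names are flagged rather than set to NaN.
    """
    out: dict[str, float] = {}
    degenerate: set[str] = set()
    _glcm_features(m, out, degenerate)
    _rl_features(
        m.glrlm_g, m.glrlm_r, m.glrlm_c, m.n_voxels, GLRLM_NAMES, out,
        degenerate, n_dirs=13,
    )
    _rl_features(
        m.glszm_g, m.glszm_z, m.glszm_c, m.n_voxels, GLSZM_NAMES, out, degenerate
    )
    _ngtdm_features(m, out, degenerate)
    return out, degenerate
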