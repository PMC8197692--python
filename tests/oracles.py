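"""Independent brute-force oracles for texture matrices, features and stats.

Everything here is written naively — explicit loops over voxel pairs,
runs, zones and permutations — and deliberately shares no code with the
package implementation it verifies.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def _inside(idx, shape):
    return all(0 <= i < s for i, s in zip(idx, shape))


def glcm_brute(levels, mask, G):
    """Dense symmetric GLCM merged over the 13 directions."""
    m = np.zeros((G, G))
    shape = mask.shape
    for idx in np.argwhere(mask):
        for d in DIRS:
            j = tuple(idx + d)
            if _inside(j, shape) and mask[j]:
                a = levels[tuple(idx)] - 1
                b = levels[j] - 1
                m[a, b] += 1
                m[b, a] += 1
    return m


def glrlm_brute_direction(levels, mask, d):
    """List of (gray level, run length) for one direction."""
    shape = mask.shape
    runs = []
    for idx in np.argwhere(mask):
        prev = tuple(idx - d)
        here = tuple(idx)
        starts = not (
            _inside(prev, shape) and mask[prev] and levels[prev] == levels[here]
        )
        if not starts:
            continue
        length = 1
        nxt = tuple(idx + d)
        while _inside(nxt, shape) and mask[nxt] and levels[nxt] == levels[here]:
            length += 1
            nxt = tuple(np.array(nxt) + d)
        runs.append((levels[here], length))
    return runs


def glrlm_brute(levels, mask, G):
    """Dense GLRLM merged over the 13 directions."""
    runs = []
    for d in DIRS:
        runs += glrlm_brute_direction(levels, mask, d)
    R = max(r for _, r in runs)
    m = np.zeros((G, R))
    for g, r in runs:
        m[g - 1, r - 1] += 1
    return m


def glszm_brute(levels, mask, G):
    """Dense GLSZM via naive BFS over 26-connected same-level zones."""
    visited = np.zeros(mask.shape, dtype=bool)
    zones = []
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if visited[idx]:
            continue
        g = levels[idx]
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                nb = tuple(np.array(cur) + d)
                if (
                    _inside(nb, mask.shape)
                    and mask[nb]
                    and not visited[nb]
                    and levels[nb] == g
                ):
                    visited[nb] = True
                    stack.append(nb)
        zones.append((g, size))
    Z = max(z for _, z in zones)
    m = np.zeros((G, Z))
    for g, z in zones:
        m[g - 1, z - 1] += 1
    return m


def ngtdm_brute(levels, mask):
    """(occupied levels, n_i, s_i) with naive 26-neighborhood averages."""
    shape = mask.shape
    per_level_n: dict[int, int] = {}
    per_level_s: dict[int, float] = {}
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        nbrs = []
        for d in NEIGHBORS_26:
            nb = tuple(np.array(idx) + d)
            if _inside(nb, shape) and mask[nb]:
                nbrs.append(levels[nb])
        if not nbrs:
            continue
        g = int(levels[idx])
        per_level_n[g] = per_level_n.get(g, 0) + 1
        per_level_s[g] = per_level_s.get(g, 0.0) + abs(g - np.mean(nbrs))
    occ = sorted(per_level_n)
    return (
        np.array(occ),
        np.array([per_level_n[g] for g in occ], dtype=float),
        np.array([per_level_s[g] for g in occ]),
    )


# ---------------------------------------------------------------------------
# naive feature formulas on dense matrices
# ---------------------------------------------------------------------------
def glcm_features_brute(mat):
    p = mat / mat.sum()
    G = p.shape[0]
    out = {}
    e = c = dis = hom = ent = 0.0
    mu = 0.0
    for i in range(G):
        for j in range(G):
            mu += p[i, j] * (i + 1)
    var = 0.0
    for i in range(G):
        for j in range(G):
            var += p[i, j] * (i + 1 - mu) ** 2
    corr = 0.0
    shade = prom = 0.0
    for i in range(G):
        for j in range(G):
            pij = p[i, j]
            e += pij**2
            c += pij * (i - j) ** 2
            dis += pij * abs(i - j)
            hom += pij / (1 + abs(i - j))
            if pij > 0:
                ent -= pij * math.log2(pij)
            corr += pij * (i + 1) * (j + 1)
            s = (i + 1) + (j + 1) - 2 * mu
            shade += pij * s**3
            prom += pij * s**4
    out["glcm_energy"] = e
    out["glcm_contrast"] = c
    out["glcm_dissimilarity"] = dis
    out["glcm_homogeneity"] = hom
    out["glcm_entropy"] = ent
    out["glcm_variance"] = var
    out["glcm_correlation"] = (corr - mu * mu) / var if var > 0 else 0.0
    out["glcm_cluster_shade"] = shade
    out["glcm_cluster_prominence"] = prom
    return out


def rl_features_brute(mat, n_voxels, prefix, names, n_dirs=1):
    nr = mat.sum()
    p = mat / nr
    G, R = mat.shape
    vals = {n: 0.0 for n in names}
    glsum = mat.sum(axis=1)
    rlsum = mat.sum(axis=0)
    mu_g = sum(p[g, r] * (g + 1) for g in range(G) for r in range(R))
    mu_r = sum(p[g, r] * (r + 1) for g in range(G) for r in range(R))
    for g in range(G):
        for r in range(R):
            pg = p[g, r]
            gl, rl = g + 1.0, r + 1.0
            vals[names[0]] += pg / rl**2
            vals[names[1]] += pg * rl**2
            vals[names[5]] += pg / gl**2
            vals[names[6]] += pg * gl**2
            vals[names[7]] += pg / (gl**2 * rl**2)
            vals[names[8]] += pg * gl**2 / rl**2
            vals[names[9]] += pg * rl**2 / gl**2
            vals[names[10]] += pg * gl**2 * rl**2
            vals[names[11]] += pg * (gl - mu_g) ** 2
            vals[names[12]] += pg * (rl - mu_r) ** 2
    vals[names[2]] = (glsum**2).sum() / nr
    vals[names[3]] = (rlsum**2).sum() / nr
    vals[names[4]] = nr / (n_voxels * n_dirs)
    return vals


def ngtdm_features_brute(occ, n_i, s_i):
    N = n_i.sum()
    p = n_i / N
    ngp = len(occ)
    out = {}
    ps = float((p * s_i).sum())
    out["ngtdm_coarseness"] = 1.0 / ps if ps > 0 else 1e6
    con = 0.0
    for a in range(ngp):
        for b in range(ngp):
            con += p[a] * p[b] * (occ[a] - occ[b]) ** 2
    out["ngtdm_contrast"] = (
        con / (ngp * (ngp - 1)) * s_i.sum() / N if ngp > 1 else 0.0
    )
    den = 0.0
    for a in range(ngp):
        for b in range(ngp):
            den += abs(occ[a] * p[a] - occ[b] * p[b])
    out["ngtdm_busyness"] = ps / den if den > 0 else 0.0
    comp = 0.0
    for a in range(ngp):
        for b in range(ngp):
            comp += (
                abs(occ[a] - occ[b])
                * (p[a] * s_i[a] + p[b] * s_i[b])
                / (p[a] + p[b])
            )
    out["ngtdm_complexity"] = comp / N
    stren = 0.0
    for a in range(ngp):
        for b in range(ngp):
            stren += (p[a] + p[b]) * (occ[a] - occ[b]) ** 2
    ssum = s_i.sum()
    out["ngtdm_strength"] = stren / ssum if ssum > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------
def wilcoxon_enumeration(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    # midranks
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def spearman_permutation(a, b):
    """(r, two-sided p) by exhaustive permutation of one margin's ranks."""
    from scipy.stats import rankdata

    ra, rb = rankdata(a), rankdata(b)
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    denom = math.sqrt((ra_c**2).sum() * (rb_c**2).sum())
    r_obs = (ra_c * rb_c).sum() / denom
    count = total = 0
    for perm in itertools.permutations(range(len(b))):
        rp = rb_c[list(perm)]
        if abs((ra_c * rp).sum() / denom) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total
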