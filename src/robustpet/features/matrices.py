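"""3D texture-matrix construction: GLCM, GLRLM, GLSZM, NGTDM.

All matrices are built from a :class:`~robustpet.preprocessing.DiscretizedVolume`
(integer gray levels 1..G inside a mask):

* GLCM — gray-level co-occurrence: symmetric accumulation over the 13
  unique 3D directions at distance 1, merged by summation; pairs crossing
  the mask boundary are ignored.
* GLRLM — gray-level run lengths along the same 13 directions, merged.
* GLSZM — gray-level size zones, one matrix, 26-connected zones.
* NGTDM — neighborhood gray-tone differences over the 26-neighborhood.

Because a fixed-bin-width quantizer can produce thousands of levels, the
matrices are stored in coordinate (COO) form — ``(level indices, counts)``
arrays — with dense accessors for verification.  Feature formulas consume
the COO form directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ..preprocessing import DiscretizedVolume

__all__ = ["DIRECTIONS_13", "TextureMatrixSet", "build_matrices"]

#: The 13 unique 3D direction vectors (26 neighbors modulo sign).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def _offset_slices(shape, off):
    """Slices (src, dst) such that dst = src + off, both inside the array."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


@dataclass
class TextureMatrixSet:
    """COO texture matrices plus NGTDM vectors for one discretized volume."""

    n_levels: int
    n_voxels: int
    # GLCM: symmetric pair counts, both orders included
    glcm_i: np.ndarray
    glcm_j: np.ndarray
    glcm_c: np.ndarray
    # GLRLM merged over directions: (gray level, run length, count)
    glrlm_g: np.ndarray
    glrlm_r: np.ndarray
    glrlm_c: np.ndarray
    # GLSZM: (gray level, zone size, count)
    glszm_g: np.ndarray
    glszm_z: np.ndarray
    glszm_c: np.ndarray
    # NGTDM per occupied level: counts n_i, probabilities p_i, sums s_i
    ngtdm_levels: np.ndarray
    ngtdm_n: np.ndarray
    ngtdm_s: np.ndarray

    # -- dense accessors (verification / small fixtures) -------------------
    def glcm_dense(self, normalized: bool = True) -> np.ndarray:
        G = self.n_levels
        m = np.zeros((G, G))
        np.add.at(m, (self.glcm_i - 1, self.glcm_j - 1), self.glcm_c)
        if normalized and m.sum() > 0:
            m /= m.sum()
        return m

    def glrlm_dense(self) -> np.ndarray:
        G = self.n_levels
        R = int(self.glrlm_r.max()) if self.glrlm_r.size else 1
        m = np.zeros((G, R))
        np.add.at(m, (self.glrlm_g - 1, self.glrlm_r - 1), self.glrlm_c)
        return m

    def glszm_dense(self) -> np.ndarray:
        G = self.n_levels
        Z = int(self.glszm_z.max()) if self.glszm_z.size else 1
        m = np.zeros((G, Z))
        np.add.at(m, (self.glszm_g - 1, self.glszm_z - 1), self.glszm_c)
        return m

    @property
    def ngtdm_p(self) -> np.ndarray:
        tot = self.ngtdm_n.sum()
        return self.ngtdm_n / tot if tot > 0 else self.ngtdm_n.astype(float)


def _crop_to_mask(levels: np.ndarray, mask: np.ndarray, pad: int = 1):
    idx = np.nonzero(mask)
    sl = tuple(
        slice(max(int(i.min()) - pad, 0), min(int(i.max()) + 1 + pad, s))
        for i, s in zip(idx, mask.shape)
    )
    return levels[sl], mask[sl]


def _glcm(levels, mask):
    G1 = int(levels.max()) + 1
    codes = []
    for d in DIRECTIONS_13:
        s_src, s_dst = _offset_slices(mask.shape, d)
        valid = mask[s_src] & mask[s_dst]
        a = levels[s_src][valid].astype(np.int64)
        b = levels[s_dst][valid].astype(np.int64)
        codes.append(a * G1 + b)
        codes.append(b * G1 + a)  # symmetric accumulation
    if codes:
        allcodes = np.concatenate(codes)
    else:
        allcodes = np.empty(0, dtype=np.int64)
    uniq, counts = np.unique(allcodes, return_counts=True)
    return uniq // G1, uniq % G1, counts.astype(float)


def _glrlm_direction(levels, mask, d):
    """Run (level, length) pairs along one direction, runs truncated at the
    mask boundary.  Run index is propagated iteratively along the direction;
    the number of sweeps is bounded by the longest run."""
    shape = mask.shape
    s_src, s_dst = _offset_slices(shape, d)
    pred_same = np.zeros(shape, dtype=bool)
    pred_same[s_dst] = (
        mask[s_src] & mask[s_dst] & (levels[s_src] == levels[s_dst])
    )
    succ_same = np.zeros(shape, dtype=bool)
    succ_same[s_src] = pred_same[s_dst]
    t = np.zeros(shape, dtype=np.int32)
    while True:
        t_new = np.zeros_like(t)
        t_new[s_dst] = np.where(pred_same[s_dst], t[s_src] + 1, 0)
        if np.array_equal(t_new, t):
            break
        t = t_new
    ends = mask & ~succ_same
    return levels[ends].astype(np.int64), (t[ends] + 1).astype(np.int64)


def _glrlm(levels, mask):
    base = int(mask.sum()) + 2  # run length < base
    codes = []
    for d in DIRECTIONS_13:
        g, r = _glrlm_direction(levels, mask, d)
        codes.append(g * base + r)
    allcodes = np.concatenate(codes)
    uniq, counts = np.unique(allcodes, return_counts=True)
    return uniq // base, uniq % base, counts.astype(float)


def glrlm_per_direction(disc: DiscretizedVolume):
    """Per-direction GLRLM triplets (g, r, count) — for conservation checks."""
    levels, mask = _crop_to_mask(disc.levels, disc.mask)
    out = []
    for d in DIRECTIONS_13:
        g, r = _glrlm_direction(levels, mask, d)
        base = int(mask.sum()) + 2
        uniq, counts = np.unique(g * base + r, return_counts=True)
        out.append((uniq // base, uniq % base, counts.astype(float)))
    return out


def _glszm(levels, mask):
    nv = int(mask.sum())
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(nv)
    rows, cols = [], []
    for d in DIRECTIONS_13:
        s_src, s_dst = _offset_slices(mask.shape, d)
        valid = mask[s_src] & mask[s_dst] & (levels[s_src] == levels[s_dst])
        rows.append(idx[s_src][valid])
        cols.append(idx[s_dst][valid])
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    graph = coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(nv, nv)
    )
    n_comp, lab = connected_components(graph, directed=False)
    sizes = np.bincount(lab, minlength=n_comp)
    lev_flat = levels[mask]
    # level of each component = level of its first member
    comp_level = np.zeros(n_comp, dtype=np.int64)
    comp_level[lab[::-1]] = lev_flat[::-1]
    base = nv + 2
    uniq, counts = np.unique(comp_level * base + sizes, return_counts=True)
    return uniq // base, uniq % base, counts.astype(float)


def _ngtdm(levels, mask):
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    m = mask.astype(float)
    nbr_sum = ndimage.convolve(levels * m, kernel, mode="constant")
    nbr_cnt = ndimage.convolve(m, kernel, mode="constant")
    valid = mask & (nbr_cnt > 0)
    abar = np.zeros(mask.shape)
    abar[valid] = nbr_sum[valid] / nbr_cnt[valid]
    diff = np.abs(levels - abar)
    lev_v = levels[valid]
    occupied, inv = np.unique(lev_v, return_inverse=True)
    n_i = np.bincount(inv).astype(float)
    s_i = np.bincount(inv, weights=diff[valid])
    return occupied, n_i, s_i


def build_matrices(disc: DiscretizedVolume) -> TextureMatrixSet:
    """Build all four texture matrices from a discretized volume."""
    levels, mask = _crop_to_mask(disc.levels, disc.mask)
    levels = np.where(mask, levels, 0)
    gi, gj, gc = _glcm(levels, mask)
    rg, rr, rc = _glrlm(levels, mask)
    zg, zz, zc = _glszm(levels, mask)
    nl, nn, ns = _ngtdm(levels, mask)
    return TextureMatrixSet(
        n_levels=disc.n_levels,
        n_voxels=int(mask.sum()),
        glcm_i=gi, glcm_j=gj, glcm_c=gc,
        glrlm_g=rg, glrlm_r=rr, glrlm_c=rc,
        glszm_g=zg, glszm_z=zz, glszm_c=zc,
        ngtdm_levels=nl, ngtdm_n=nn, ngtdm_s=ns,
    )
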