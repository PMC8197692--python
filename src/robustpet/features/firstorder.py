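"""First-order SUV statistics and the cumulative SUV-volume histogram.

Skewness is m3/m2^1.5 and kurtosis m4/m2^2 (Pearson convention: a normal
distribution has kurtosis 3).  Intensity entropy and energy-like measures
use the fixed-bin-width histogram of the configured quantizer, so they —
unlike skewness/kurtosis/aucCSH — are not invariant to global intensity
scaling.
"""

from __future__ import annotations

import numpy as np

from ..preprocessing import discretize_fbw

__all__ = ["first_order", "auc_csh", "skewness", "kurtosis"]

#: Integration grid for the cumulative SUV-volume histogram.
_CSH_GRID = np.linspace(0.0, 1.0, 1000)


def skewness(values: np.ndarray) -> float:
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.all(x == x.flat[0]):
        return 0.0
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0:
        return 0.0
    m3 = ((x - m) ** 3).mean()
    return float(m3 / m2**1.5)


def kurtosis(values: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis; 3 for a normal distribution."""
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.all(x == x.flat[0]):
        return 0.0
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0:
        return 0.0
    m4 = ((x - m) ** 4).mean()
    return float(m4 / m2**2)


def auc_csh(values: np.ndarray) -> float:
    """Area under the cumulative SUV-volume histogram.

    CSH(t) = fraction of voxels whose min-max normalized intensity is >= t,
    integrated over t in [0, 1] by the trapezoid rule on a fixed
    1000-point grid.  Invariant under positive affine intensity maps.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    xn = np.sort((x - lo) / (hi - lo))
    csh = 1.0 - np.searchsorted(xn, _CSH_GRID, side="left") / xn.size
    return float(np.trapezoid(csh, _CSH_GRID))


def first_order(values: np.ndarray, hist_bin_width: float = 0.01) -> dict[str, float]:
    """The first-order / histogram feature block.

    Returns a name -> value dict; degenerate entries (constant input) are
    handled by the caller via the degeneracy report.
    """
    x = np.asarray(values, dtype=float)
    feats = {
        "suv_mean": float(x.mean()),
        "suv_max": float(x.max()),
        "suv_min": float(x.min()),
        "suv_median": float(np.median(x)),
        "suv_sd": float(x.std()),
        "suv_energy": float((x**2).sum()),
        "suv_entropy": _histogram_entropy(x, hist_bin_width),
        "skewness": skewness(x),
        "kurtosis": kurtosis(x),
        "auc_csh": auc_csh(x),
    }
    return feats


def _histogram_entropy(x: np.ndarray, W: float) -> float:
    disc = discretize_fbw(x, W)
    counts = np.bincount(disc.levels[disc.mask])
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())
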