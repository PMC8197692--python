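"""Intensity discretization and wavelet band-pass filtering.

Three quantizers map in-mask voxel intensities to integer gray levels
``1..G`` before texture-matrix construction:

* ``fbw``  — fixed bin width W anchored at the in-mask minimum
  (level = floor((x - min)/W) + 1); sensitive to global intensity scaling.
* ``fbn``  — fixed number of bins N over the in-mask range; invariant to
  positive affine intensity transforms.
* ``equal_prob`` — histogram-equalization (mid-CDF) mapping to N levels;
  invariant to any strictly monotone intensity transform.

This asymmetry of invariance classes is the mechanism by which different
discretization choices yield different feature reproducibility.

The wavelet band-pass filter performs a one-level 3D separable DWT,
weights the six mixed (band-pass) sub-bands relative to LLL/HHH, and
inverts the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import ConfigurationError
from .grid import VolumeGrid

__all__ = [
    "QuantizerSpec",
    "WaveletSpec",
    "DiscretizedVolume",
    "discretize_fbw",
    "discretize_fbn",
    "equal_prob_quantize",
    "discretize",
    "wavelet_bandpass",
]

_BANDPASS_KEYS = {"aad", "ada", "daa", "add", "dad", "dda"}  # mixed sub-bands


@dataclass
class QuantizerSpec:
    """Discretization choice: method plus its W (fbw) or N (fbn/equal_prob)."""

    method: str = "fbw"
    W: float = 0.01
    N: int = 64

    def __post_init__(self) -> None:
        if self.method not in ("fbw", "fbn", "equal_prob"):
            raise ConfigurationError(f"unknown quantizer method {self.method!r}")
        if self.W <= 0 or self.N < 2:
            raise ConfigurationError("require W > 0 and N >= 2")


@dataclass
class WaveletSpec:
    """One-level 3D wavelet filter with band-pass weighting.

    ``bandpass_weight_ratio`` = 0.5 encodes the 1:2 weighting of band-pass
    sub-bands relative to the LLL/HHH sub-bands.
    """

    basis: str = "sym4"
    bandpass_weight_ratio: float = 0.5
    levels: int = 1

    def __post_init__(self) -> None:
        if self.bandpass_weight_ratio <= 0:
            raise ConfigurationError("bandpass weight ratio must be positive")
        if self.levels != 1:
            raise ConfigurationError("only one decomposition level is supported")


@dataclass
class DiscretizedVolume:
    """Integer gray levels (1..n_levels) for the in-mask voxels.

    ``levels`` is a full-size int array with 0 outside the mask; ``record``
    stores the mapping (bin edges, or the value->level table for the
    equal-probability quantizer).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    method: str
    record: dict = field(default_factory=dict)

    def in_mask(self) -> np.ndarray:
        return self.levels[self.mask]


def _embed(levels_flat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros(mask.shape, dtype=np.int64)
    out[mask] = levels_flat
    return out


def discretize_fbw(
    values: np.ndarray, W: float, mask: np.ndarray | None = None
) -> DiscretizedVolume:
    """Fixed-bin-width discretization anchored at the in-mask minimum."""
    if W <= 0:
        raise ConfigurationError("W must be positive")
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    x = values[mask]
    lo, hi = float(x.min()), float(x.max())
    G = int(np.floor((hi - lo) / W)) + 1
    lev = np.floor((x - lo) / W).astype(np.int64) + 1
    np.clip(lev, 1, G, out=lev)  # the maximum maps to the top level
    return DiscretizedVolume(
        _embed(lev, mask), mask, G, "fbw", {"W": W, "min": lo, "max": hi}
    )


def discretize_fbn(
    values: np.ndarray, N: int, mask: np.ndarray | None = None
) -> DiscretizedVolume:
    """Fixed-bin-number discretization over the in-mask range."""
    if N < 2:
        raise ConfigurationError("N must be >= 2")
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    x = values[mask]
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        lev = np.ones(x.shape, dtype=np.int64)
    else:
        lev = np.floor(N * (x - lo) / (hi - lo)).astype(np.int64) + 1
        np.clip(lev, 1, N, out=lev)
    return DiscretizedVolume(
        _embed(lev, mask), mask, N, "fbn", {"N": N, "min": lo, "max": hi}
    )


def equal_prob_quantize(
    values: np.ndarray, N: int, mask: np.ndarray | None = None
) -> DiscretizedVolume:
    """Equal-probability (histogram-equalization) quantization to N levels.

    Each distinct value v is mapped by the mid-point of its empirical CDF
    step: level(v) = floor(N * (F(v-) + F(v)) / 2) + 1.  The mapping is
    monotone, depends only on ranks (hence is invariant under strictly
    monotone intensity transforms), and the occupancy imbalance per level
    is bounded by the largest tie group.
    """
    if N < 2:
        raise ConfigurationError("N must be >= 2")
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    x = values[mask]
    n = x.size
    uniq, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    mid = cum - counts / 2.0  # mid-CDF count of each distinct value
    lev_of_uniq = np.floor(N * mid / n).astype(np.int64) + 1
    np.clip(lev_of_uniq, 1, N, out=lev_of_uniq)
    lev = lev_of_uniq[inv]
    return DiscretizedVolume(
        _embed(lev, mask),
        mask,
        N,
        "equal_prob",
        {"N": N, "values": uniq, "levels": lev_of_uniq},
    )


def discretize(
    values: np.ndarray, spec: QuantizerSpec, mask: np.ndarray | None = None
) -> DiscretizedVolume:
    """Dispatch to the quantizer named in ``spec``."""
    if spec.method == "fbw":
        return discretize_fbw(values, spec.W, mask)
    if spec.method == "fbn":
        return discretize_fbn(values, spec.N, mask)
    return equal_prob_quantize(values, spec.N, mask)


def wavelet_bandpass(
    volume: VolumeGrid | np.ndarray,
    spec: WaveletSpec | None = None,
) -> VolumeGrid | np.ndarray:
    """One-level 3D wavelet decomposition with band-pass re-weighting.

    The six sub-bands mixing low- and high-pass axes (LLH, LHL, HLL, LHH,
    HLH, HHL) are multiplied by ``spec.bandpass_weight_ratio``; LLL and HHH
    keep weight 1.  The inverse transform is cropped back to the input
    shape.  With all weights equal to 1 the round trip is lossless to
    numerical tolerance.
    """
    spec = spec or WaveletSpec()
    arr = volume.values if isinstance(volume, VolumeGrid) else np.asarray(volume)
    if min(arr.shape) < 8:
        raise ConfigurationError("wavelet filtering requires >= 8 voxels per axis")
    coeffs = pywt.dwtn(arr, spec.basis, mode="symmetric")
    for key in coeffs:
        if key in _BANDPASS_KEYS:
            coeffs[key] = coeffs[key] * spec.bandpass_weight_ratio
    rec = pywt.idwtn(coeffs, spec.basis, mode="symmetric")
    rec = rec[tuple(slice(0, s) for s in arr.shape)]
    if isinstance(volume, VolumeGrid):
        return volume.copy(values=rec)
    return rec
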