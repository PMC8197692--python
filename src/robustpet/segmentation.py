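"""Lesion delineation: pseudo-CT region growing, PET 40% threshold, COA.

Three methods are compared by the robustness pipeline:

* ``segment_region_growing`` — ground truth: Gaussian-smoothed pseudo-CT,
  region growing from a seed within an HU window (default 50–150 HU).
* ``segment_threshold40`` — fixed threshold at 40% of the maximum uptake
  inside a per-lesion ROI; invariant to global intensity scaling.
* ``segment_coa`` — contrast-oriented adaptive threshold
  T = a·I70 + b·bg, where I70 is the mean over the 70%-of-max isocontour
  and bg the automatically estimated background level.  The published
  algorithm's exact threshold function is scanner-calibrated; the linear
  contrast model with configurable (a, b) reproduces its structure and a
  calibration helper fits (a, b) on homogeneous simulated spheres.

All masks are single 26-connected components containing the lesion's
maximum-uptake voxel; threshold ties are included (closed threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .errors import BackgroundError, EmptyMaskError, SegmentationError
from .grid import VolumeGrid

__all__ = [
    "SeedROI",
    "SegMask",
    "COAParams",
    "segment_region_growing",
    "segment_threshold40",
    "segment_coa",
    "estimate_background",
    "recovery_coefficient",
    "calibrate_coa",
]

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class SeedROI:
    """Per-lesion box search region in voxel coordinates (half-open slices)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    @classmethod
    def from_mask(cls, mask: np.ndarray, margin_vox: int = 0) -> "SeedROI":
        idx = np.nonzero(mask)
        if len(idx[0]) == 0:
            raise SegmentationError("cannot build an ROI from an empty mask")
        lo = tuple(max(int(i.min()) - margin_vox, 0) for i in idx)
        hi = tuple(
            min(int(i.max()) + 1 + margin_vox, s)
            for i, s in zip(idx, mask.shape)
        )
        return cls(lo, hi)

    def slices(self, shape=None, dilate_vox: int = 0) -> tuple[slice, slice, slice]:
        lo = [max(low - dilate_vox, 0) for low in self.lo]
        hi = list(self.hi)
        if shape is None:
            hi = [h + dilate_vox for h in hi]
        else:
            hi = [min(h + dilate_vox, s) for h, s in zip(hi, shape)]
        return tuple(slice(a, b) for a, b in zip(lo, hi))

    def to_mask(self, shape, dilate_vox: int = 0) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slices(shape, dilate_vox)] = True
        return out

    def scaled(self, factor: float) -> "SeedROI":
        """Map the ROI to a grid coarser/finer by ``factor`` (>1 = coarser)."""
        lo = tuple(int(np.floor(low / factor)) for low in self.lo)
        hi = tuple(int(np.ceil(h / factor)) for h in self.hi)
        return SeedROI(lo, hi)


@dataclass
class SegMask:
    """A binary delineation on its source grid, tagged by method."""

    mask: np.ndarray
    spacing_mm: float
    method: str  # {gt, th40, coa, roi}

    @property
    def volume_ml(self) -> float:
        return float(self.mask.sum()) * self.spacing_mm**3 / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class COAParams:
    """Linear contrast model T = a·I70 + b·bg of the adaptive threshold."""

    a: float = 0.5
    b: float = 0.5
    iso_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise SegmentationError("COA weights must be nonnegative")
        if not (0.0 < self.iso_fraction < 1.0):
            raise SegmentationError("iso_fraction must lie in (0, 1)")


def _connected_to(mask: np.ndarray, seed_idx: tuple[int, ...]) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=_STRUCT26)
    lab = labels[seed_idx]
    if lab == 0:
        raise SegmentationError("seed voxel not inside the thresholded set")
    return labels == lab


def segment_region_growing(
    pseudo_ct: VolumeGrid,
    seed: tuple[int, int, int],
    window: tuple[float, float] = (50.0, 150.0),
    smooth_radius_vox: float = 2.0,
) -> SegMask:
    """Region growing on the Gaussian-denoised pseudo-CT (ground truth).

    The image is smoothed with a Gaussian of sigma = radius/2 voxels, then
    all 26-connected voxels whose smoothed value lies inside ``window``
    are grown from ``seed``.
    """
    lo, hi = window
    smoothed = ndimage.gaussian_filter(pseudo_ct.values, smooth_radius_vox / 2.0)
    if not (lo <= smoothed[tuple(seed)] <= hi):
        raise SegmentationError(
            f"seed value {smoothed[tuple(seed)]:.1f} outside window {window}"
        )
    inside = (smoothed >= lo) & (smoothed <= hi)
    return SegMask(_connected_to(inside, tuple(seed)), pseudo_ct.spacing_mm, "gt")


def segment_threshold40(
    pet: VolumeGrid,
    roi: SeedROI,
    fraction: float = 0.40,
    roi_dilation_vox: int = 2,
) -> SegMask:
    """Fixed threshold at ``fraction`` of the ROI maximum intensity.

    The mask is the 26-connected component containing the maximum voxel
    among voxels >= T, restricted to the ROI dilated by 2 voxels so that
    blur-spread lesion edges are not clipped.
    """
    region = roi.to_mask(pet.shape, roi_dilation_vox)
    sub = roi.to_mask(pet.shape)
    vals = pet.values[sub]
    vmax = float(vals.max())
    if vals.min() == vmax:
        warnings.warn("ROI has constant intensity; returning the whole ROI",
                      stacklevel=2)
        return SegMask(sub, pet.spacing_mm, "th40")
    T = fraction * vmax
    flat = np.where(sub, pet.values, -np.inf)
    seed_idx = np.unravel_index(int(np.argmax(flat)), pet.shape)
    candidates = region & (pet.values >= T)
    return SegMask(_connected_to(candidates, seed_idx), pet.spacing_mm, "th40")


def estimate_background(
    pet: VolumeGrid,
    exclusion: np.ndarray | None = None,
    air_fraction: float = 0.05,
    n_bins: int = 256,
) -> float:
    """Robust background level: histogram mode outside lesions and air.

    Candidate voxels lie outside all exclusion masks and above an air
    threshold (``air_fraction`` × median positive value).  The mode is the
    center of the fullest bin of a histogram clipped to the 0.1–99.9
    percentile range.
    """
    values = pet.values
    cand = np.ones(values.shape, dtype=bool) if exclusion is None else ~exclusion
    positive = values[values > 0]
    if positive.size == 0:
        raise BackgroundError("image has no positive voxels")
    air = air_fraction * float(np.median(positive))
    cand &= values > air
    x = values[cand]
    if x.size == 0:
        raise BackgroundError("no candidate background voxels")
    lo, hi = np.percentile(x, [0.1, 99.9])
    if hi <= lo:
        return float(x[0])
    hist, edges = np.histogram(x[(x >= lo) & (x <= hi)], bins=n_bins)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def segment_coa(
    pet: VolumeGrid,
    roi: SeedROI,
    params: COAParams | None = None,
    bg: float | None = None,
    roi_dilation_vox: int = 2,
) -> SegMask:
    """Contrast-oriented adaptive threshold segmentation.

    I70 = mean of ROI voxels >= iso_fraction × ROI max;
    T = a·I70 + b·bg.  ``bg`` defaults to the automatic whole-image
    background estimate.  Raises :class:`EmptyMaskError` when T reaches
    the ROI maximum (the pipeline reports it per lesion and continues).
    """
    params = params or COAParams()
    if bg is None:
        bg = estimate_background(pet, roi.to_mask(pet.shape, roi_dilation_vox))
    if bg < 0:
        raise SegmentationError("background level must be nonnegative")
    sub = roi.to_mask(pet.shape)
    vals = pet.values[sub]
    vmax = float(vals.max())
    i70 = float(vals[vals >= params.iso_fraction * vmax].mean())
    T = params.a * i70 + params.b * bg
    if T >= vmax:
        raise EmptyMaskError(
            f"COA threshold {T:.3g} >= ROI maximum {vmax:.3g}"
        )
    region = roi.to_mask(pet.shape, roi_dilation_vox)
    flat = np.where(sub, pet.values, -np.inf)
    seed_idx = np.unravel_index(int(np.argmax(flat)), pet.shape)
    candidates = region & (pet.values >= T)
    return SegMask(_connected_to(candidates, seed_idx), pet.spacing_mm, "coa")


def recovery_coefficient(mask: SegMask, ref: SegMask) -> float:
    """Volume recovery coefficient RC = volume(mask) / volume(ref)."""
    if ref.volume_ml <= 0:
        raise SegmentationError("reference mask has zero volume")
    return mask.volume_ml / ref.volume_ml


def calibrate_coa(
    cases: list[tuple[VolumeGrid, SeedROI, float]],
    bg: float | None = None,
    iso_fraction: float = 0.70,
) -> COAParams:
    """Fit (a, b) minimizing the relative volume error on reference cases.

    ``cases`` holds (pet, roi, true_volume_ml) triples — typically
    homogeneous blurred spheres spanning the clinical size range.
    """

    def cost(ab):
        a, b = ab
        if a < 0 or b < 0:
            return 1e6
        err = 0.0
        for pet, roi, v_true in cases:
            try:
                m = segment_coa(pet, roi, COAParams(a, b, iso_fraction), bg)
                err += ((m.volume_ml - v_true) / v_true) ** 2
            except EmptyMaskError:
                err += 4.0
        return err

    res = optimize.minimize(
        cost, x0=[0.5, 0.5], method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4},
    )
    a, b = res.x
    return COAParams(float(max(a, 0.0)), float(max(b, 0.0)), iso_fraction)
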