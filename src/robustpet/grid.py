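"""Isotropic 3D image container and resampling helpers.

``VolumeGrid`` is the universal carrier for activity maps, simulated PET
images and pseudo-CT volumes.  The voxel-center convention is used
throughout: world coordinate of voxel index ``i`` along an axis is
``origin + (i + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["VolumeGrid", "block_downsample", "block_downsample_mask"]


@dataclass
class VolumeGrid:
    """A 3D scalar image on an isotropic grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (activity concentration, SUV, or HU-like units).
    spacing_mm : float
        Isotropic voxel edge length in millimetres.
    origin_mm : ndarray, shape (3,)
        World coordinate of the corner of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("VolumeGrid requires a 3D array")
        if self.spacing_mm <= 0:
            raise ConfigurationError("spacing_mm must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("VolumeGrid values must be finite")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return float(self.spacing_mm**3 / 1000.0)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers (broadcastable)."""
        axes = []
        for ax, n in enumerate(self.shape):
            c = self.origin_mm[ax] + (np.arange(n) + 0.5) * self.spacing_mm
            shape = [1, 1, 1]
            shape[ax] = n
            axes.append(c.reshape(shape))
        return tuple(axes)  # type: ignore[return-value]

    def copy(self, values: np.ndarray | None = None) -> "VolumeGrid":
        return VolumeGrid(
            self.values.copy() if values is None else values,
            self.spacing_mm,
            self.origin_mm.copy(),
        )

    def check_nonnegative(self) -> None:
        if np.any(self.values < 0):
            raise ConfigurationError("activity/PET volume has negative values")


def block_downsample(grid: VolumeGrid, factor: int) -> VolumeGrid:
    """Average ``factor``³ blocks of voxels into one coarse voxel.

    Trailing voxels that do not fill a complete block are discarded, so the
    coarse grid stays aligned with the fine grid corner.  Block averaging
    conserves the mean and therefore total activity of complete blocks.
    """
    if factor < 1 or int(factor) != factor:
        raise ConfigurationError("downsample factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return grid.copy()
    n = [s - s % factor for s in grid.shape]
    v = grid.values[: n[0], : n[1], : n[2]]
    v = v.reshape(
        n[0] // factor, factor, n[1] // factor, factor, n[2] // factor, factor
    ).mean(axis=(1, 3, 5))
    return VolumeGrid(v, grid.spacing_mm * factor, grid.origin_mm.copy())


def block_downsample_mask(
    mask: np.ndarray, factor: int, threshold: float = 0.5
) -> np.ndarray:
    """Downsample a binary mask by block-mean >= ``threshold`` (majority)."""
    if factor == 1:
        return mask.copy()
    n = [s - s % factor for s in mask.shape]
    m = mask[: n[0], : n[1], : n[2]].astype(float)
    m = m.reshape(
        n[0] // factor, factor, n[1] // factor, factor, n[2] // factor, factor
    ).mean(axis=(1, 3, 5))
    return m >= threshold
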