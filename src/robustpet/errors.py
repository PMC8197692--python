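"""Exception hierarchy for the robustpet pipeline.

Errors are grouped so the CLI can map them onto distinct exit codes:
configuration problems, data/geometry problems, and numerical failures.
"""


class RobustPETError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RobustPETError):
    """Invalid scene, experiment, or parameter configuration."""


class DegenerateGeometryError(ConfigurationError):
    """A lesion or insert is too small for the requested grid."""


class NormalizationError(RobustPETError):
    """Background normalization impossible (empty mask / non-positive mean)."""


class SegmentationError(RobustPETError):
    """Segmentation failed (bad seed, empty candidate set, ...)."""


class EmptyMaskError(SegmentationError):
    """An adaptive threshold exceeded the ROI maximum; no voxel selected."""


class BackgroundError(SegmentationError):
    """Automatic background estimation had no candidate voxels."""
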