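"""Feature-vector assembly: the 133-feature roster for one (image, mask).

The roster is the first-order/histogram/shape block (13 features) plus the
40 texture features computed in three preprocessing variants:

* plain  — configured quantizer (default fixed bin width W = 0.01);
* ``wf_`` — wavelet band-pass filtered image (1:2 sub-band weighting),
  then the configured quantizer;
* ``q_``  — equal-probability quantization (default 64 levels) of the raw
  in-mask intensities.

13 + 3 × 40 = 133.  The exact published roster of named features is not
public; this canonical roster reproduces the stated families, prefixes and
count, and is exported to YAML so a study records exactly what it computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ..grid import VolumeGrid
from ..preprocessing import (
    QuantizerSpec,
    WaveletSpec,
    discretize,
    equal_prob_quantize,
    wavelet_bandpass,
)
from .firstorder import first_order
from .matrices import build_matrices
from .shape import shape_features
from .texture import TEXTURE_NAMES, texture_features

__all__ = ["FeatureConfig", "FeatureVector", "extract_all", "roster_names",
           "dump_roster", "FIRST_ORDER_NAMES", "SHAPE_NAMES"]

FIRST_ORDER_NAMES = (
    "suv_mean", "suv_max", "suv_min", "suv_median", "suv_sd",
    "suv_energy", "suv_entropy", "skewness", "kurtosis", "auc_csh",
)
SHAPE_NAMES = ("volume_ml", "sphericity", "max_diameter_mm")


@dataclass
class FeatureConfig:
    """Quantizer, wavelet and equal-probability settings for extraction."""

    quantizer: QuantizerSpec = field(default_factory=QuantizerSpec)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    q_levels: int = 64

    def metadata(self) -> dict:
        return {
            "quantizer.method": self.quantizer.method,
            "quantizer.W": self.quantizer.W,
            "quantizer.N": self.quantizer.N,
            "wavelet.basis": self.wavelet.basis,
            "wavelet.ratio": self.wavelet.bandpass_weight_ratio,
            "q_levels": self.q_levels,
        }


def roster_names() -> list[str]:
    """The canonical ordered 133-feature roster."""
    names = list(FIRST_ORDER_NAMES) + list(SHAPE_NAMES)
    for prefix in ("", "wf_", "q_"):
        names += [prefix + n for n in TEXTURE_NAMES]
    return names


def dump_roster(path: str | Path) -> Path:
    """Write the roster (with family/prefix annotations) as YAML."""
    entries = []
    for name in roster_names():
        prefix = "none"
        base = name
        if name.startswith("wf_"):
            prefix, base = "WF", name[3:]
        elif name.startswith("q_"):
            prefix, base = "Q", name[2:]
        family = (
            "shape" if base in SHAPE_NAMES
            else "first_order" if base in FIRST_ORDER_NAMES
            else base.split("_")[0]
        )
        entries.append({"name": name, "family": family, "preprocessing": prefix})
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump({"n_features": len(entries), "features": entries}, fh,
                       sort_keys=False)
    return path


@dataclass
class FeatureVector:
    """Ordered feature name -> value map with a degeneracy report."""

    names: list[str]
    values: dict[str, float]
    degenerate: set[str]
    provenance: dict[str, object] = field(default_factory=dict)

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in self.names])

    def __len__(self) -> int:
        return len(self.names)


def extract_all(
    pet: VolumeGrid,
    mask: np.ndarray,
    config: FeatureConfig | None = None,
    mask_method: str = "gt",
) -> FeatureVector:
    """Compute the full roster for one image/mask pair.

    Deterministic: two runs on the same inputs produce bit-identical
    vectors.  Degenerate sub-features (constant intensities, single-voxel
    masks) are recorded in ``degenerate`` rather than silently NaN.
    """
    config = config or FeatureConfig()
    if not mask.any():
        raise ValueError("cannot extract features from an empty mask")
    values: dict[str, float] = {}
    degenerate: set[str] = set()

    x = pet.values[mask]
    values.update(shape_features(mask, pet.spacing_mm))
    if x.size < 2:
        for n in FIRST_ORDER_NAMES:
            values[n] = float(x[0]) if n in (
                "suv_mean", "suv_max", "suv_min", "suv_median") else 0.0
            if n not in ("suv_mean", "suv_max", "suv_min", "suv_median"):
                degenerate.add(n)
    else:
        values.update(first_order(x, hist_bin_width=config.quantizer.W))
        if x.max() == x.min():
            degenerate.update({"skewness", "kurtosis", "auc_csh"})

    # plain / wavelet-filtered / equal-probability texture variants
    variants: list[tuple[str, np.ndarray]] = [("", pet.values)]
    wf = wavelet_bandpass(pet.values, config.wavelet)
    variants.append(("wf_", wf))
    for prefix, img in variants:
        disc = discretize(img, config.quantizer, mask)
        feats, degen = texture_features(build_matrices(disc))
        for k, v in feats.items():
            values[prefix + k] = v
        degenerate.update(prefix + k for k in degen)
    disc_q = equal_prob_quantize(pet.values, config.q_levels, mask)
    feats, degen = texture_features(build_matrices(disc_q))
    for k, v in feats.items():
        values["q_" + k] = v
    degenerate.update("q_" + k for k in degen)

    names = roster_names()
    assert set(names) == set(values), "roster/values mismatch"
    return FeatureVector(
        names,
        values,
        degenerate,
        provenance={"mask_method": mask_method, **config.metadata()},
    )
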