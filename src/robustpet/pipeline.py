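"""End-to-end in-silico robustness study.

Reproduces the four-factor study design on digital phantoms:

* ``system``       — analog-like (FWHM 4.8 mm, higher noise) vs
  digital-like (FWHM 4.2 mm, lower noise) system on the NEMA-IQ phantom
  (6 hot spheres segmented at 40%, 10 background spheres with fixed
  ground-truth masks).
* ``voxel``        — 2 mm vs 4 mm reconstruction voxels from one parent
  activity map, same system, NEMA-IQ phantom.
* ``artifact``     — cheese phantom with vs without a metal insert
  (streak + PET bias emulation), 6 fillable tubes × 2 configurations,
  40% segmentation; includes the RC_water recovery coefficients.
* ``segmentation`` — the 27 heterogeneous lesions delineated by the
  pseudo-CT ground truth, the 40% threshold and the contrast-oriented
  algorithm; the factor comparison is 40% vs COA, with ground-truth
  comparisons and the Bland–Altman volume bias reported alongside.

Every simulation is seeded from one master seed; reruns with the same
configuration are bit-identical.  Each lesion sits in its own warm
background tile for the segmentation factor (equivalent to one large
phantom for a uniform background, but far cheaper to blur).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError
from .features import FeatureConfig, extract_all, roster_names
from .grid import VolumeGrid, block_downsample_mask
from .io import dump_yaml, write_json
from .phantoms import (
    GroundTruth,
    PhantomScene,
    SystemModel,
    apply_system,
    build_scene,
    cheese_scene,
    heterogeneous_lesion_set,
    inject_streaks,
    lesion_bed_scene,
    nema_scene,
    normalize_background,
)
from .segmentation import (
    COAParams,
    SeedROI,
    segment_coa,
    segment_region_growing,
    segment_threshold40,
)
from .stats import RobustnessReport, StatConfig, build_report

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_experiment",
    "run_factor_system",
    "run_factor_voxel",
    "run_factor_artifact",
    "run_factor_segmentation",
    "run_scaled_pair_study",
    "simulate_normalized_pet",
]


def _seed(master: int, k: int) -> int:
    return (master * 100003 + 7919 * k + 1) % (2**31)


@dataclass
class ArmSpec:
    """One protocol arm: PSF, voxel size and noise level."""

    psf_fwhm_mm: float = 4.8
    voxel_size_mm: float = 2.0
    noise_sd: float = 0.05


@dataclass
class StudyConfig:
    """All knobs of the default four-factor study."""

    seed: int = 0
    sim_spacing_mm: float = 1.0
    analog: ArmSpec = field(default_factory=lambda: ArmSpec(4.8, 2.0, 0.05))
    digital: ArmSpec = field(default_factory=lambda: ArmSpec(4.2, 2.0, 0.03))
    voxel_fine: ArmSpec = field(default_factory=lambda: ArmSpec(4.8, 2.0, 0.05))
    voxel_coarse: ArmSpec = field(default_factory=lambda: ArmSpec(4.8, 4.0, 0.05))
    artifact_metal: str = "steel"
    artifact_amplitude: float = 0.15
    lesion_to_bg_contrast: float = 10.0
    bg_margin_mm: float = 10.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    stats: StatConfig = field(default_factory=StatConfig)
    coa: COAParams = field(default_factory=COAParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    report: RobustnessReport
    tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    extras: dict[str, object] = field(default_factory=dict)
    manifest: dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------
def _background_mask_out(
    truth: GroundTruth,
    pet: VolumeGrid,
    factor: int,
    margin_mm: float,
) -> np.ndarray:
    """Warm-background mask on the output grid: inside the phantom body,
    away from every lesion and from the body edge by ``margin_mm``."""
    les = block_downsample_mask(truth.lesion_labels > 0, factor, threshold=0.01)
    # body := positive-activity support on the output grid
    body = pet.values > 0.05 * np.median(pet.values[pet.values > 0])
    it = max(int(np.ceil(margin_mm / pet.spacing_mm)), 1)
    bg = ndimage.binary_erosion(body, iterations=it) & ~ndimage.binary_dilation(
        les, iterations=it
    )
    if not bg.any():
        bg = body & ~les
    return bg


def simulate_normalized_pet(
    scene: PhantomScene,
    sys: SystemModel,
    sim_spacing_mm: float = 1.0,
    bg_margin_mm: float = 10.0,
):
    """Scene -> activity -> degraded PET -> background-normalized PET.

    Returns (pet, truth, pseudo_ct, factor) where ``factor`` is the
    integer fine-to-coarse resampling ratio.
    """
    activity, truth, ct = build_scene(scene, sim_spacing_mm)
    pet = apply_system(activity, sys)
    factor = int(round(sys.voxel_size_mm / sim_spacing_mm))
    bg = _background_mask_out(truth, pet, factor, bg_margin_mm)
    pet = normalize_background(pet, bg)
    return pet, truth, ct, factor


def _feature_tables(
    rows: dict[str, "FeatureVectorLike"],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    names = roster_names()
    values = pd.DataFrame(
        {lid: [fv.values[n] for n in names] for lid, fv in rows.items()},
        index=names,
    ).T
    valid = pd.DataFrame(
        {lid: [n not in fv.degenerate for n in names] for lid, fv in rows.items()},
        index=names,
    ).T
    return values, valid


def _extract_arm(
    pet: VolumeGrid,
    masks: dict[str, np.ndarray],
    cfg: FeatureConfig,
    mask_method: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = {
        lid: extract_all(pet, m, cfg, mask_method) for lid, m in masks.items()
    }
    return _feature_tables(rows)


def _truth_masks_out(truth: GroundTruth, factor: int) -> dict[str, np.ndarray]:
    return {
        lid: block_downsample_mask(m, factor) for lid, m in truth.masks.items()
    }


def _th40_masks(
    pet: VolumeGrid, truth_out: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    out = {}
    for lid, tm in truth_out.items():
        roi = SeedROI.from_mask(tm, margin_vox=2)
        out[lid] = segment_threshold40(pet, roi).mask
    return out


# ---------------------------------------------------------------------------
# factor experiments
# ---------------------------------------------------------------------------
def run_factor_system(cfg: StudyConfig):
    """Analog vs digital system on the NEMA-IQ phantom."""
    scene = nema_scene(sphere_contrast=cfg.lesion_to_bg_contrast)
    tables = []
    for i, arm in enumerate((cfg.analog, cfg.digital)):
        sys = SystemModel(
            arm.psf_fwhm_mm, arm.voxel_size_mm, arm.noise_sd,
            seed=_seed(cfg.seed, 10 + i),
        )
        pet, truth, _, factor = simulate_normalized_pet(
            scene, sys, cfg.sim_spacing_mm, cfg.bg_margin_mm
        )
        truth_out = _truth_masks_out(truth, factor)
        hot = {k: v for k, v in truth_out.items() if k.startswith("S")}
        bg_spheres = {k: v for k, v in truth_out.items() if k.startswith("B")}
        masks = {**_th40_masks(pet, hot), **bg_spheres}
        tables.append(_extract_arm(pet, masks, cfg.features, "th40+gt"))
    return tables[0], tables[1]


def run_factor_voxel(cfg: StudyConfig):
    """2 mm vs 4 mm reconstruction from one parent activity map."""
    scene = nema_scene(sphere_contrast=cfg.lesion_to_bg_contrast)
    activity, truth, _ = build_scene(scene, cfg.sim_spacing_mm)
    tables = []
    for i, arm in enumerate((cfg.voxel_fine, cfg.voxel_coarse)):
        sys = SystemModel(
            arm.psf_fwhm_mm, arm.voxel_size_mm, arm.noise_sd,
            seed=_seed(cfg.seed, 20 + i),
        )
        pet = apply_system(activity, sys)
        factor = int(round(arm.voxel_size_mm / cfg.sim_spacing_mm))
        bg = _background_mask_out(truth, pet, factor, cfg.bg_margin_mm)
        pet = normalize_background(pet, bg)
        truth_out = _truth_masks_out(truth, factor)
        hot = {k: v for k, v in truth_out.items() if k.startswith("S")}
        bg_spheres = {k: v for k, v in truth_out.items() if k.startswith("B")}
        masks = {**_th40_masks(pet, hot), **bg_spheres}
        tables.append(_extract_arm(pet, masks, cfg.features, "th40+gt"))
    return tables[0], tables[1]


def run_factor_artifact(cfg: StudyConfig):
    """Cheese phantom with vs without a metal insert (both configurations)."""
    rows_with: dict = {}
    rows_without: dict = {}
    rc_water: dict[str, float] = {}
    for ci, config in enumerate(("pc", "hn")):
        scene = cheese_scene(
            config=config,
            metal=cfg.artifact_metal,
            tube_contrast=cfg.lesion_to_bg_contrast,
            artifact_amplitude=cfg.artifact_amplitude,
        )
        sys = SystemModel(
            cfg.analog.psf_fwhm_mm, cfg.analog.voxel_size_mm,
            cfg.analog.noise_sd, seed=_seed(cfg.seed, 30 + ci),
        )
        activity, truth, ct = build_scene(scene, cfg.sim_spacing_mm)
        pet_clean = apply_system(activity, sys)
        factor = int(round(sys.voxel_size_mm / cfg.sim_spacing_mm))
        assert scene.artifact is not None
        _, pet_metal = inject_streaks(ct, pet_clean, scene.artifact)
        bg = _background_mask_out(truth, pet_clean, factor, cfg.bg_margin_mm)
        pet_clean = normalize_background(pet_clean, bg)
        pet_metal = normalize_background(pet_metal, bg)
        truth_out = _truth_masks_out(truth, factor)
        for lid, tm in truth_out.items():
            roi = SeedROI.from_mask(tm, margin_vox=2)
            m_clean = segment_threshold40(pet_clean, roi)
            m_metal = segment_threshold40(pet_metal, roi)
            key = f"{config}_{lid}"
            rows_without[key] = extract_all(
                pet_clean, m_clean.mask, cfg.features, "th40")
            rows_with[key] = extract_all(
                pet_metal, m_metal.mask, cfg.features, "th40")
            rc_water[key] = m_metal.volume_ml / m_clean.volume_ml
    ta, va = _feature_tables(rows_with)
    tb, vb = _feature_tables(rows_without)
    return (ta, va), (tb, vb), rc_water


def run_factor_segmentation(cfg: StudyConfig):
    """GT vs 40% vs COA on the 27 heterogeneous lesions.

    Returns per-method feature tables, per-method volumes, and the list of
    lesions where COA produced an empty mask (excluded pairwise).
    """
    lesions = heterogeneous_lesion_set(lesion_to_bg=cfg.lesion_to_bg_contrast)
    sys_arm = cfg.analog
    rows: dict[str, dict] = {"gt": {}, "th40": {}, "coa": {}}
    volumes: dict[str, dict[str, float]] = {"gt": {}, "th40": {}, "coa": {}}
    failures: list[str] = []
    for li, (lid, lesion) in enumerate(lesions):
        scene = lesion_bed_scene(lesion, lid)
        sys = SystemModel(
            sys_arm.psf_fwhm_mm, sys_arm.voxel_size_mm, sys_arm.noise_sd,
            seed=_seed(cfg.seed, 100 + li),
        )
        pet, truth, ct, factor = simulate_normalized_pet(
            scene, sys, cfg.sim_spacing_mm, cfg.bg_margin_mm
        )
        tmask = truth.masks[lid]
        seed_vox = tuple(
            int(round(c)) for c in ndimage.center_of_mass(tmask)
        )
        gt_fine = segment_region_growing(ct, seed_vox)
        gt_mask = block_downsample_mask(gt_fine.mask, factor)
        roi = SeedROI.from_mask(block_downsample_mask(tmask, factor), 2)
        m40 = segment_threshold40(pet, roi)
        masks = {"gt": gt_mask, "th40": m40.mask}
        volumes["gt"][lid] = gt_fine.volume_ml
        volumes["th40"][lid] = m40.volume_ml
        try:
            mcoa = segment_coa(pet, roi, cfg.coa)
            masks["coa"] = mcoa.mask
            volumes["coa"][lid] = mcoa.volume_ml
        except EmptyMaskError:
            failures.append(lid)
        for method, m in masks.items():
            rows[method][lid] = extract_all(pet, m, cfg.features, method)
    tables = {m: _feature_tables(rows[m]) for m in ("gt", "th40", "coa")}
    return tables, volumes, failures


# ---------------------------------------------------------------------------
# the full study and the scaled-pair mechanism study
# ---------------------------------------------------------------------------
def _align(ta: pd.DataFrame, tb: pd.DataFrame):
    common = ta.index.intersection(tb.index)
    return ta.loc[common], tb.loc[common]


def run_experiment(
    cfg: StudyConfig | None = None, outdir: str | Path | None = None
) -> StudyResult:
    """Run all four factor comparisons and build the robustness report."""
    cfg = cfg or StudyConfig()
    t0 = time.time()
    stages: dict[str, float] = {}

    (sa, sva), (sb, svb) = run_factor_system(cfg)
    stages["system"] = time.time() - t0

    (va_t, va_v), (vb_t, vb_v) = run_factor_voxel(cfg)
    stages["voxel"] = time.time() - t0

    (aa_t, aa_v), (ab_t, ab_v), rc_water = run_factor_artifact(cfg)
    stages["artifact"] = time.time() - t0

    seg_tables, volumes, coa_failures = run_factor_segmentation(cfg)
    stages["segmentation"] = time.time() - t0

    (g_t, g_v) = seg_tables["gt"]
    (f_t, f_v) = seg_tables["th40"]
    (c_t, c_v) = seg_tables["coa"]
    f_t2, c_t2 = _align(f_t, c_t)
    f_v2, c_v2 = f_v.loc[f_t2.index], c_v.loc[c_t2.index]

    tables = {
        "system": (sa, sb),
        "voxel": (va_t, vb_t),
        "artifact": (aa_t, ab_t),
        "segmentation": (f_t2, c_t2),
    }
    valids = {
        "system": (sva, svb),
        "voxel": (va_v, vb_v),
        "artifact": (aa_v, ab_v),
        "segmentation": (f_v2, c_v2),
    }
    report = build_report(tables, cfg.stats, valids)

    # ground-truth comparisons and the volume-bias analysis
    from .stats import PairedSample, bland_altman, compare_tables

    g40_t, g40_b = _align(g_t, f_t)
    gcoa_t, gcoa_b = _align(g_t, c_t)
    gt_vs_th40 = compare_tables(g40_b, g40_t, cfg.stats, None, None)
    gt_vs_coa = compare_tables(gcoa_b, gcoa_t, cfg.stats, None, None)

    extras: dict[str, object] = {"rc_water": rc_water, "volumes": volumes,
                                 "coa_failures": coa_failures}
    ids40 = [lid for lid in volumes["gt"] if lid in volumes["th40"]]
    bias40, ci40, _ = bland_altman(PairedSample(
        "volume_ml",
        np.array([volumes["th40"][i] for i in ids40]),
        np.array([volumes["gt"][i] for i in ids40]),
    ))
    idsc = [lid for lid in volumes["gt"] if lid in volumes["coa"]]
    biasc, cic, _ = bland_altman(PairedSample(
        "volume_ml",
        np.array([volumes["coa"][i] for i in idsc]),
        np.array([volumes["gt"][i] for i in idsc]),
    ))
    extras["volume_bias_th40_pct"] = bias40
    extras["volume_bias_coa_pct"] = biasc
    extras["gt_vs_th40"] = gt_vs_th40
    extras["gt_vs_coa"] = gt_vs_coa
    extras["rc_v_series"] = {
        lid: volumes["th40"][lid] / volumes["gt"][lid]
        for lid in ids40 if lid.startswith("V")
    }
    stages["total"] = time.time() - t0

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seconds": stages,
        "files": [],
    }
    result = StudyResult(report, tables, extras, manifest)
    if outdir is not None:
        _write_outputs(result, cfg, Path(outdir))
    return result


def _write_outputs(result: StudyResult, cfg: StudyConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for factor, (ta, tb) in result.tables.items():
        for arm, t in (("A", ta), ("B", tb)):
            p = outdir / f"features_{factor}_{arm}.csv"
            t.to_csv(p)
            files.append(p.name)
        p = outdir / f"details_{factor}.csv"
        result.report.details_frame(factor).to_csv(p)
        files.append(p.name)
    p = outdir / "robustness_flags.csv"
    result.report.to_frame().to_csv(p)
    files.append(p.name)
    summary = result.report.summary()
    summary["volume_bias_th40_pct"] = result.extras.get("volume_bias_th40_pct")
    summary["volume_bias_coa_pct"] = result.extras.get("volume_bias_coa_pct")
    summary["rc_water"] = result.extras.get("rc_water")
    summary["rc_v_series"] = result.extras.get("rc_v_series")
    summary["coa_failures"] = result.extras.get("coa_failures")
    write_json(summary, outdir / "summary.json")
    files.append("summary.json")
    result.manifest["files"] = sorted(files)
    write_json(result.manifest, outdir / "manifest.json")
    dump_yaml(cfg.to_dict(), outdir / "config.yaml")


def run_scaled_pair_study(
    seed: int = 0,
    scale: float = 1.3,
    noise_sd: float = 0.02,
    cfg: StudyConfig | None = None,
    lesions: list | None = None,
):
    """Two-arm mechanism study: protocol B = A with intensities × ``scale``.

    The 27 heterogeneous lesion images (2% noise by default) are extracted
    under their ground-truth masks; arm B rescales the voxel intensities
    of the very same images.  Features invariant to positive affine (or
    monotone) intensity maps must come out robust; fixed-bin-width
    features shift systematically and should not.
    """
    cfg = cfg or StudyConfig(seed=seed)
    if lesions is None:
        lesions = heterogeneous_lesion_set(lesion_to_bg=cfg.lesion_to_bg_contrast)
    rows_a: dict = {}
    rows_b: dict = {}
    for li, (lid, lesion) in enumerate(lesions):
        scene = lesion_bed_scene(lesion, lid)
        sys = SystemModel(
            cfg.analog.psf_fwhm_mm, cfg.analog.voxel_size_mm, noise_sd,
            seed=_seed(seed, 200 + li),
        )
        pet, truth, ct, factor = simulate_normalized_pet(
            scene, sys, cfg.sim_spacing_mm, cfg.bg_margin_mm
        )
        gt_mask = block_downsample_mask(truth.masks[lid], factor)
        rows_a[lid] = extract_all(pet, gt_mask, cfg.features, "gt")
        pet_b = pet.copy(values=pet.values * scale)
        rows_b[lid] = extract_all(pet_b, gt_mask, cfg.features, "gt")
    ta, va = _feature_tables(rows_a)
    tb, vb = _feature_tables(rows_b)
    report = build_report({"scale": (ta, tb)}, cfg.stats, {"scale": (va, vb)})
    return report, (ta, tb), (va, vb)
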