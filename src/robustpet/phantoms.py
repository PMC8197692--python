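"""Digital phantoms with exact ground truth, plus system-degradation operators.

Three phantom families are provided, mirroring the physical setups used for
EARL-style robustness studies:

* NEMA-IQ-like phantom — six fillable spheres (0.5–25 cc) in a warm
  background plus ten background spheres (5.7–8.4 cc) used as homogeneous
  pseudo-lesions.
* Heterogeneous lesion bed — 27 multilayer lesions: 18 three-layer lesions
  (patterns L1–L6 at layer contrast ratios (10,5), (8,4) and (4,2), all with
  diameter > 3×FWHM) and 9 two-layer cylinders (V1–V8 spanning 1–15.6 ml at
  inner/outer contrast 6, plus one extra L6).  The low layer sits at 10×
  the background concentration.
* Cheese-phantom — a 30 cm solid-water cylinder with tissue/metal inserts
  and six fillable tubes (3×33 ml, 3×11 ml), with or without metal-streak
  artifacts, in "prostate" (pc) and "head-and-neck" (hn) configurations.

Degradation is modelled on the reconstructed image: Gaussian point-spread
blur, grid-aligned block-average resampling to the reconstruction voxel
size, additive Gaussian noise relative to the background level, and
background-SUV normalization.  Metal artifacts are emulated as alternating
radial streaks on the pseudo-CT and a proportional multiplicative bias on
the PET near the metal, with amplitude scaling with insert density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    NormalizationError,
)
from .grid import VolumeGrid, block_downsample

__all__ = [
    "Sphere",
    "Cylinder",
    "LesionLayerSpec",
    "PhantomScene",
    "SystemModel",
    "ArtifactSpec",
    "GroundTruth",
    "build_scene",
    "apply_system",
    "normalize_background",
    "inject_streaks",
    "multilayer_lesion",
    "two_layer_cylinder",
    "homogeneous_sphere",
    "heterogeneous_lesion_set",
    "nema_scene",
    "cheese_scene",
    "lesion_bed_scene",
    "INSERT_DENSITIES",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian point-spread function.
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493

#: Densities (g/cm^3) of commercially available cheese-phantom inserts.
INSERT_DENSITIES = {
    "lung": 0.480,
    "solid_water": 1.000,
    "inner_bone": 1.136,
    "cb2_30": 1.332,
    "cortical_bone": 1.882,
    "aluminum": 2.800,
    "titanium": 4.500,
    "steel": 7.700,
}

#: HU assigned to the alginate-like lesion material on the pseudo-CT; must
#: sit inside the 50–150 HU region-growing initialization window.
LESION_HU = 100.0
AIR_HU = -1000.0


# ---------------------------------------------------------------------------
# geometric solids (voxelized by the center-point rule)
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float

    def contains(self, xs, ys, zs) -> np.ndarray:
        r2 = (
            (xs - self.center_mm[0]) ** 2
            + (ys - self.center_mm[1]) ** 2
            + (zs - self.center_mm[2]) ** 2
        )
        return r2 <= self.radius_mm**2

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm**3 / 1000.0

    def shifted(self, offset) -> "Sphere":
        c = tuple(np.asarray(self.center_mm) + np.asarray(offset))
        return Sphere(c, self.radius_mm)

    @property
    def extent_mm(self) -> float:
        return 2 * self.radius_mm


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned circular cylinder (axis along z by default)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    height_mm: float
    axis: int = 2

    def contains(self, xs, ys, zs) -> np.ndarray:
        coords = [xs, ys, zs]
        ax = coords.pop(self.axis)
        c = list(self.center_mm)
        c_ax = c.pop(self.axis)
        r2 = (coords[0] - c[0]) ** 2 + (coords[1] - c[1]) ** 2
        return (r2 <= self.radius_mm**2) & (np.abs(ax - c_ax) <= self.height_mm / 2)

    @property
    def volume_ml(self) -> float:
        return np.pi * self.radius_mm**2 * self.height_mm / 1000.0

    def shifted(self, offset) -> "Cylinder":
        c = tuple(np.asarray(self.center_mm) + np.asarray(offset))
        return Cylinder(c, self.radius_mm, self.height_mm, self.axis)

    @property
    def extent_mm(self) -> float:
        return max(2 * self.radius_mm, self.height_mm)


Solid = Sphere | Cylinder


# ---------------------------------------------------------------------------
# lesion and scene specifications
# ---------------------------------------------------------------------------
@dataclass
class LesionLayerSpec:
    """A lesion as an ordered list of solids painted outermost-first.

    Later (inner) solids overwrite earlier ones, so layers are mutually
    exclusive and jointly exhaustive within the outer envelope.  The true
    lesion volume is the analytic volume of the envelope.
    """

    pattern: str
    solids: list[Solid]
    concentrations: list[float]
    envelope_volume_ml: float

    def __post_init__(self) -> None:
        if len(self.solids) != len(self.concentrations):
            raise ConfigurationError("one concentration per solid is required")
        if any(c <= 0 for c in self.concentrations):
            raise ConfigurationError("layer concentrations must be positive")

    @property
    def extent_mm(self) -> float:
        return self.solids[0].extent_mm

    def shifted(self, offset) -> "LesionLayerSpec":
        return LesionLayerSpec(
            self.pattern,
            [s.shifted(offset) for s in self.solids],
            list(self.concentrations),
            self.envelope_volume_ml,
        )


@dataclass
class ArtifactSpec:
    """Streak/bias artifact description for the cheese phantom.

    ``amplitude`` is the dimensionless relative PET bias next to a
    stainless-steel insert; lighter metals scale it down by
    (density - 1) / (density_steel - 1).
    """

    metal_centers_mm: list[tuple[float, float, float]]
    material: str = "steel"
    amplitude: float = 0.15
    ct_amplitude_hu: float = 800.0
    n_spokes: int = 12
    decay_r0_mm: float = 30.0

    @property
    def density(self) -> float:
        return INSERT_DENSITIES[self.material]

    @property
    def density_scale(self) -> float:
        ref = INSERT_DENSITIES["steel"]
        return max(self.density - 1.0, 0.0) / (ref - 1.0)


@dataclass
class PhantomScene:
    """Declarative phantom layout: background + lesions (+ inserts)."""

    kind: str  # {nema, cheese, lesion_bed}
    background_concentration: float
    box_mm: tuple[float, float, float]
    lesions: list[tuple[str, LesionLayerSpec]] = field(default_factory=list)
    inserts: list[tuple[str, Solid]] = field(default_factory=list)  # (material, solid)
    body: Solid | None = None  # phantom body; None = whole box is background
    artifact: ArtifactSpec | None = None

    def __post_init__(self) -> None:
        if self.background_concentration <= 0:
            raise ConfigurationError("background concentration must be positive")
        ids = [lid for lid, _ in self.lesions]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate lesion ids in scene")


@dataclass
class SystemModel:
    """Image-domain model of a PET system + reconstruction protocol."""

    psf_fwhm_mm: float = 4.8
    voxel_size_mm: float = 2.0
    noise_sd: float = 0.0  # relative to background mean
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2.0 <= self.psf_fwhm_mm <= 10.0):
            raise ConfigurationError("psf_fwhm_mm outside plausible PET range 2-10 mm")
        if self.voxel_size_mm <= 0 or self.noise_sd < 0:
            raise ConfigurationError("invalid SystemModel parameters")


@dataclass
class GroundTruth:
    """Exact per-lesion masks and volumes on the simulation grid."""

    grid: VolumeGrid  # geometry reference (spacing/origin); values unused
    masks: dict[str, np.ndarray]
    true_volumes_ml: dict[str, float]
    layer_labels: np.ndarray  # 0 = background, k = layer index of some lesion
    lesion_labels: np.ndarray  # 0 = background, i+1 = i-th lesion

    def lesion_ids(self) -> list[str]:
        return list(self.masks)

    def background_mask(self, margin_mm: float = 0.0) -> np.ndarray:
        """Voxels outside every lesion, optionally eroded away from lesions."""
        from scipy.ndimage import binary_dilation

        union = self.lesion_labels > 0
        if margin_mm > 0:
            it = int(np.ceil(margin_mm / self.grid.spacing_mm))
            union = binary_dilation(union, iterations=it)
        return ~union


# ---------------------------------------------------------------------------
# lesion factories
# ---------------------------------------------------------------------------
def homogeneous_sphere(
    radius_mm: float, concentration: float, center=(0.0, 0.0, 0.0)
) -> LesionLayerSpec:
    s = Sphere(tuple(center), radius_mm)
    return LesionLayerSpec("sphere", [s], [concentration], s.volume_ml)


def two_layer_cylinder(
    volume_ml: float,
    c_low: float,
    contrast: float = 6.0,
    inner_fraction: float = 0.125,
    center=(0.0, 0.0, 0.0),
) -> LesionLayerSpec:
    """Two-layer cylinder: outer shell at C_L, coaxial inner core at C_H.

    Height equals diameter; the inner cylinder is a half-scale copy
    (1/8 of the volume by default).  ``contrast`` is C_H / C_L.
    """
    r = (volume_ml * 1000.0 / (2 * np.pi)) ** (1.0 / 3.0)
    outer = Cylinder(tuple(center), r, 2 * r)
    fi = inner_fraction ** (1.0 / 3.0)
    inner = Cylinder(tuple(center), r * fi, 2 * r * fi)
    return LesionLayerSpec(
        "two_layer_cylinder",
        [outer, inner],
        [c_low, c_low * contrast],
        outer.volume_ml,
    )


def multilayer_lesion(
    pattern: str,
    ratios: tuple[float, float],
    c_low: float,
    diameter_mm: float = 40.0,
    height_mm: float = 40.0,
    center=(0.0, 0.0, 0.0),
) -> LesionLayerSpec:
    """Three-layer cylindrical lesion, patterns L1–L6.

    ``ratios`` = (C_H/C_L, C_M/C_L).  The exact layer geometries of the
    physical lesions are not published; the shipped layouts are a
    parameterized best-effort set sharing their qualitative structure:
    L1–L3 place the high concentration peripherally or in axial stacks,
    L4–L6 place it in inner regions (the configurations for which simple
    PET thresholds reject the cold periphery).
    """
    rh, rm = ratios
    ch, cm, cl = c_low * rh, c_low * rm, c_low
    c = np.asarray(center, dtype=float)
    r = diameter_mm / 2.0
    h = height_mm
    outer = Cylinder(tuple(c), r, h)

    def cyl(rad, hh, offset=(0, 0, 0)):
        return Cylinder(tuple(c + np.asarray(offset, float)), rad, hh)

    if pattern == "L1":  # outward-hot concentric: H outer, M mid, L core
        solids = [outer, cyl(0.75 * r, h), cyl(0.45 * r, h)]
        concs = [ch, cm, cl]
    elif pattern == "L2":  # M outer, H mid ring, L core
        solids = [outer, cyl(0.75 * r, h), cyl(0.45 * r, h)]
        concs = [cm, ch, cl]
    elif pattern == "L3":  # axial stack: H / M / L slabs
        solids = [outer, cyl(r, 2 * h / 3), cyl(r, h / 3, (0, 0, -h / 3))]
        concs = [ch, cm, cl]
    elif pattern == "L4":  # inward-hot concentric: L outer, M mid, H core
        solids = [outer, cyl(0.75 * r, h), cyl(0.45 * r, h)]
        concs = [cl, cm, ch]
    elif pattern == "L5":  # eccentric hot core in a medium disc, cold shell
        solids = [outer, cyl(0.75 * r, h), cyl(0.3 * r, 0.6 * h, (0.35 * r, 0, 0))]
        concs = [cl, cm, ch]
    elif pattern == "L6":  # axial stack with hot inner core
        solids = [outer, cyl(r, 2 * h / 3, (0, 0, h / 6)), cyl(0.5 * r, h / 3)]
        concs = [cl, cm, ch]
    else:
        raise ConfigurationError(f"unknown multilayer pattern {pattern!r}")
    return LesionLayerSpec(pattern, solids, concs, outer.volume_ml)


#: Lesion volumes of the two-layer cylinder series V1..V8 (ml).
V_SERIES_VOLUMES_ML = (1.0, 1.9, 3.0, 4.5, 6.5, 9.0, 12.2, 15.6)

#: Layer contrast ratio triplets (C_H/C_L, C_M/C_L) of the multilayer group.
MULTILAYER_RATIOS = ((10.0, 5.0), (8.0, 4.0), (4.0, 2.0))


def heterogeneous_lesion_set(
    c_bg: float = 1.0, lesion_to_bg: float = 10.0
) -> list[tuple[str, LesionLayerSpec]]:
    """The 27-lesion heterogeneous set.

    18 multilayer lesions (L1–L6 × three ratio triplets) plus the
    two-layer cylinder series V1–V8 and one extra L6 instance, all with
    C_L = ``lesion_to_bg`` × C_bg.
    """
    c_low = lesion_to_bg * c_bg
    out: list[tuple[str, LesionLayerSpec]] = []
    for rh, rm in MULTILAYER_RATIOS:
        for k in range(1, 7):
            lid = f"L{k}_r{int(rh)}"
            out.append((lid, multilayer_lesion(f"L{k}", (rh, rm), c_low)))
    for i, v in enumerate(V_SERIES_VOLUMES_ML, start=1):
        out.append((f"V{i}", two_layer_cylinder(v, c_low)))
    out.append(("L6_extra", multilayer_lesion("L6", (8.0, 4.0), c_low)))
    return out


# ---------------------------------------------------------------------------
# scene factories
# ---------------------------------------------------------------------------
#: NEMA NU 2 IQ sphere inner diameters (mm); volumes 0.5–25 cc.
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


def nema_scene(
    c_bg: float = 1.0, sphere_contrast: float = 10.0
) -> PhantomScene:
    """NEMA-IQ-like phantom: 6 hot spheres on a ring + 10 background spheres.

    The six fillable spheres follow the NEMA NU 2 diameters at
    ``sphere_contrast`` : 1 against the warm background.  Ten spheres of
    5.7–8.4 cc are additionally defined inside the background (scripted
    placement) and serve as homogeneous pseudo-lesions; they carry the
    background concentration and exist only as ground-truth masks.
    """
    box = (230.0, 230.0, 120.0)
    cx, cy, cz = box[0] / 2, box[1] / 2, box[2] / 2
    body = Cylinder((cx, cy, cz), 105.0, 110.0)
    lesions: list[tuple[str, LesionLayerSpec]] = []
    ring_r = 57.0
    for i, d in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        ang = 2 * np.pi * i / 6
        c = (cx + ring_r * np.cos(ang), cy + ring_r * np.sin(ang), cz)
        lesions.append(
            (f"S{i + 1}", homogeneous_sphere(d / 2, sphere_contrast * c_bg, c))
        )
    # 10 background spheres, 5.7-8.4 cc -> radii 11.07-12.62 mm
    vols = np.linspace(5.7, 8.4, 10)
    radii = (3 * vols * 1000.0 / (4 * np.pi)) ** (1.0 / 3.0)
    for i, r in enumerate(radii):
        ang = 2 * np.pi * i / 10 + np.pi / 10
        c = (cx + 90.0 * np.cos(ang), cy + 90.0 * np.sin(ang), cz)
        lesions.append((f"B{i + 1}", homogeneous_sphere(r, c_bg, c)))
    return PhantomScene("nema", c_bg, box, lesions, body=body)


def cheese_scene(
    config: str = "pc",
    metal: str | None = "steel",
    c_bg: float = 1.0,
    tube_contrast: float = 10.0,
    artifact_amplitude: float = 0.15,
) -> PhantomScene:
    """Cheese-phantom: solid-water cylinder with inserts and fillable tubes.

    Six fillable tubes (3 large, 33 ml; 3 small, 11 ml) and one metal (or
    solid-water reference) insert are placed on the 28 mm hole lattice in a
    "prostate" (pc, tubes clustered centrally around the metal) or
    "head-and-neck" (hn, tubes on a wider ring) arrangement.  The exact
    hole coordinates of the physical configurations are not published;
    placements are configurable, defaults below.
    """
    box = (320.0, 320.0, 200.0)
    cx, cy, cz = box[0] / 2, box[1] / 2, box[2] / 2
    body = Cylinder((cx, cy, cz), 150.0, 180.0)
    if config == "pc":
        tube_ring, metal_pos = 45.0, (cx, cy, cz)
    elif config == "hn":
        tube_ring, metal_pos = 75.0, (cx + 35.0, cy, cz)
    else:
        raise ConfigurationError(f"unknown cheese configuration {config!r}")

    lesions: list[tuple[str, LesionLayerSpec]] = []
    c_tube = tube_contrast * c_bg
    for i in range(6):
        large = i < 3
        vol = 33.0 if large else 11.0
        r = 14.0
        h = vol * 1000.0 / (np.pi * r**2)
        ang = 2 * np.pi * i / 6 + (0 if config == "pc" else np.pi / 6)
        c = (cx + tube_ring * np.cos(ang), cy + tube_ring * np.sin(ang), cz)
        tube = Cylinder(c, r, h)
        lid = f"TL{i + 1}" if large else f"TS{i - 2}"
        lesions.append(
            (lid, LesionLayerSpec("tube", [tube], [c_tube], tube.volume_ml))
        )

    inserts: list[tuple[str, Solid]] = [
        ("lung", Cylinder((cx - 110.0, cy, cz), 14.0, 70.0)),
        ("cortical_bone", Cylinder((cx + 110.0, cy, cz), 14.0, 70.0)),
    ]
    artifact = None
    material = metal if metal is not None else "solid_water"
    inserts.append((material, Cylinder(metal_pos, 14.0, 70.0)))
    if metal is not None:
        artifact = ArtifactSpec(
            [metal_pos], material=metal, amplitude=artifact_amplitude
        )
    return PhantomScene("cheese", c_bg, box, lesions, inserts, body, artifact)


def lesion_bed_scene(
    lesion: LesionLayerSpec,
    lesion_id: str = "lesion",
    c_bg: float = 1.0,
    margin_mm: float = 25.0,
) -> PhantomScene:
    """A single lesion centered in a warm background box.

    Equivalent, for a uniform background, to placing the lesion in a large
    phantom; keeping one lesion per volume keeps blurring cheap and the
    per-lesion ground truth trivially separable.
    """
    ext = lesion.extent_mm
    box = tuple(float(np.ceil(ext + 2 * margin_mm)) for _ in range(3))
    center = tuple(b / 2 for b in box)
    return PhantomScene(
        "lesion_bed", c_bg, box, [(lesion_id, lesion.shifted(center))]
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------
def _template_grid(scene: PhantomScene, spacing_mm: float) -> VolumeGrid:
    shape = tuple(int(round(b / spacing_mm)) for b in scene.box_mm)
    if min(shape) < 8:
        raise ConfigurationError("scene grid must be at least 8 voxels per axis")
    return VolumeGrid(np.zeros(shape), spacing_mm)


def build_scene(
    scene: PhantomScene,
    spacing_mm: float = 1.0,
    grid: VolumeGrid | None = None,
) -> tuple[VolumeGrid, GroundTruth, VolumeGrid]:
    """Rasterize a scene: activity map, exact ground truth, pseudo-CT.

    Voxels are assigned by the center-point rule (a voxel belongs to the
    innermost solid containing its center).  The pseudo-CT maps the lesion
    material to 100 HU (inside the 50–150 HU region-growing window),
    water/background to 0 HU, air to -1000 HU and inserts to
    1000·(density−1) HU.
    """
    if grid is None:
        grid = _template_grid(scene, spacing_mm)
    xs, ys, zs = grid.voxel_centers()
    shape = grid.shape
    vox_ml = grid.voxel_volume_ml

    if scene.body is None:
        body = np.ones(shape, dtype=bool)
    else:
        body = scene.body.contains(xs, ys, zs)
    activity = np.where(body, scene.background_concentration, 0.0)
    ct = np.where(body, 0.0, AIR_HU)

    lesion_labels = np.zeros(shape, dtype=np.int32)
    layer_labels = np.zeros(shape, dtype=np.int32)
    masks: dict[str, np.ndarray] = {}
    true_vols: dict[str, float] = {}
    occupied = np.zeros(shape, dtype=bool)
    layer_counter = 0

    for idx, (lid, lesion) in enumerate(scene.lesions, start=1):
        envelope = lesion.solids[0].contains(xs, ys, zs)
        if not envelope.any() or envelope.sum() * vox_ml < vox_ml:
            raise DegenerateGeometryError(f"lesion {lid} smaller than one voxel")
        if not (envelope <= body).all():
            raise ConfigurationError(f"lesion {lid} extends outside the phantom body")
        if (envelope & occupied).any():
            raise ConfigurationError(f"lesion {lid} overlaps a previous lesion")
        occupied |= envelope
        for solid, conc in zip(lesion.solids, lesion.concentrations):
            layer_counter += 1
            inside = solid.contains(xs, ys, zs) & envelope
            activity[inside] = conc
            layer_labels[inside] = layer_counter
        ct[envelope] = LESION_HU
        lesion_labels[envelope] = idx
        masks[lid] = envelope
        true_vols[lid] = lesion.envelope_volume_ml

    for material, solid in scene.inserts:
        inside = solid.contains(xs, ys, zs)
        if (inside & occupied).any():
            raise ConfigurationError(f"insert {material} overlaps a lesion")
        density = INSERT_DENSITIES[material]
        ct[inside] = 1000.0 * (density - 1.0)
        activity[inside] = 0.0

    truth = GroundTruth(
        grid.copy(values=np.zeros(shape)),
        masks,
        true_vols,
        layer_labels,
        lesion_labels,
    )
    return grid.copy(values=activity), truth, grid.copy(values=ct)


# ---------------------------------------------------------------------------
# degradation operators
# ---------------------------------------------------------------------------
def apply_system(activity: VolumeGrid, sys: SystemModel) -> VolumeGrid:
    """Blur by the system PSF, resample to the reconstruction grid, add noise.

    The blur sigma is FWHM / 2.3548; resampling is grid-aligned block
    averaging (the target voxel size must be an integer multiple of the
    simulation spacing); noise is additive Gaussian with standard deviation
    ``noise_sd`` × background level (median of positive voxels), clipped at
    zero.  Deterministic given ``sys.seed``.
    """
    if sys.voxel_size_mm < activity.spacing_mm - 1e-9:
        raise ConfigurationError(
            "target voxel size must be >= simulation spacing"
        )
    factor = sys.voxel_size_mm / activity.spacing_mm
    if abs(factor - round(factor)) > 1e-6:
        raise ConfigurationError(
            "target voxel size must be an integer multiple of the spacing"
        )
    if sys.psf_fwhm_mm < sys.voxel_size_mm:
        warnings.warn(
            "PSF FWHM below the target voxel size; image is undersampled",
            stacklevel=2,
        )
    sigma_vox = sys.psf_fwhm_mm * FWHM_TO_SIGMA / activity.spacing_mm
    blurred = gaussian_filter(activity.values, sigma_vox, mode="reflect")
    pet = block_downsample(activity.copy(values=blurred), int(round(factor)))
    if sys.noise_sd > 0:
        positive = pet.values[pet.values > 0]
        bg_level = float(np.median(positive)) if positive.size else 0.0
        rng = np.random.default_rng(sys.seed)
        pet.values = pet.values + rng.normal(
            0.0, sys.noise_sd * bg_level, size=pet.shape
        )
        np.clip(pet.values, 0.0, None, out=pet.values)
    return pet


def normalize_background(pet: VolumeGrid, bg_mask: np.ndarray) -> VolumeGrid:
    """Scale the image so the mean over ``bg_mask`` equals 1 exactly."""
    if not bg_mask.any():
        raise NormalizationError("background mask is empty")
    mean = float(pet.values[bg_mask].mean())
    if mean <= 0:
        raise NormalizationError("non-positive background mean")
    return pet.copy(values=pet.values / mean)


def inject_streaks(
    pseudo_ct: VolumeGrid, pet: VolumeGrid, spec: ArtifactSpec
) -> tuple[VolumeGrid, VolumeGrid]:
    """Emulate metal artifacts: CT streaks + multiplicative PET bias.

    Straight alternating positive/negative streaks (sinusoidal angular
    modulation, 1/(1+r/r0) radial decay) are added to the pseudo-CT through
    every metal center, and the PET receives a proportional multiplicative
    bias field near the metal, emulating the attenuation-correction error.
    Amplitudes scale with insert density (aluminum < titanium < steel).
    With ``amplitude == 0`` both images are returned bit-exact.
    """
    ct_out = pseudo_ct.copy()
    pet_out = pet.copy()
    if spec.amplitude == 0:
        return ct_out, pet_out
    scale = spec.density_scale
    for center in spec.metal_centers_mm:
        ct_out.values += _streak_field(
            pseudo_ct, center, spec, spec.ct_amplitude_hu * scale, phase=0.0
        )
        bias = _streak_field(
            pet, center, spec, spec.amplitude * scale, phase=np.pi / spec.n_spokes
        )
        pet_out.values *= 1.0 + bias
    np.clip(pet_out.values, 0.0, None, out=pet_out.values)
    return ct_out, pet_out


def _streak_field(
    grid: VolumeGrid, center, spec: ArtifactSpec, amplitude: float, phase: float
) -> np.ndarray:
    xs, ys, zs = grid.voxel_centers()
    dx = xs - center[0]
    dy = ys - center[1]
    r = np.sqrt(dx**2 + dy**2)
    theta = np.arctan2(dy, dx + 1e-12)
    radial = 1.0 / (1.0 + r / spec.decay_r0_mm)
    angular = np.sin(spec.n_spokes * theta + phase)
    # streaks live in the axial plane of the insert, fading along z
    dz = np.abs(zs - center[2])
    axial = np.exp(-((dz / 60.0) ** 2))
    return amplitude * angular * radial * axial
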