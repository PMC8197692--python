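# Methods

This note documents the models, defaults and numerical choices behind
`robustpet`, and what the synthetic phantoms do and do not emulate.

## Phantom simulation

All phantoms are rasterized on a fine isotropic grid (default 1 mm) by the
center-point rule: a voxel belongs to the innermost solid containing its
center. Voxelization error therefore vanishes as the grid is refined
(tested at 2, 1 and 0.5 mm), and both reconstruction-voxel arms (2 mm and
4 mm) are derived from one parent activity map. World coordinates follow
the voxel-center convention `world = origin + (index + 0.5) · spacing`.

**Heterogeneous lesions.** The 27-lesion set comprises 18 three-layer
cylindrical lesions — six spatial patterns × three layer-contrast triplets
(C_H/C_L, C_M/C_L) ∈ {(10,5), (8,4), (4,2)} — and 9 two-layer lesions: the
cylinder series V1–V8 with total volumes 1 … 15.6 ml at inner/outer
contrast 6, plus one extra inward-hot pattern. The exact layer geometries
of the physical lesions were never published; the shipped layouts are a
parameterized default set in which patterns L1–L3 place the high
concentration peripherally or in axial stacks and L4–L6 place it in inner
regions — the configurations for which threshold-based PET segmentation
rejects the cold periphery. The multilayer lesions are 40 mm in diameter
(> 3× the widest PSF FWHM) so that their interior statistics are not
dominated by partial-volume effects. The low layer sits at 10× the
background concentration; background concentration is arbitrary because
images are background-normalized afterwards. The V-series intermediate
volumes follow an approximately geometric progression between the 1 and
15.6 ml endpoints; each lesion's core is a half-scale copy of its envelope
(1/8 of the volume).

**NEMA-IQ-like phantom.** Six fillable spheres at the standard NEMA NU 2
diameters (10–37 mm) on a 57 mm ring at 10:1 contrast against the warm
background, plus ten background spheres of 5.7–8.4 cc placed by script on
a 90 mm ring; the latter carry background activity and exist as fixed
ground-truth masks serving as homogeneous pseudo-lesions.

**Cheese phantom.** A 30 cm diameter, 18 cm thick solid-water cylinder
with a metal insert (aluminum/titanium/steel, densities 2.800/4.500/7.700
g/cm³), two tissue inserts, and six fillable tubes (3 × 33 ml, 3 × 11 ml)
in a central ("prostate") or ring ("head-and-neck") arrangement. Hole
coordinates of the physical configurations are not published; placements
are configurable.

**Pseudo-CT.** Water/background at 0 HU, air at −1000 HU, the
alginate-like lesion material at 100 HU (inside the 50–150 HU
region-growing window), and inserts at 1000·(ρ−1) HU.

## Degradation operators

`apply_system` blurs with a Gaussian PSF (σ = FWHM/2.3548, reflective
boundaries, which keep total activity conserved to ≪ 0.5 % for interior
objects), block-averages onto the reconstruction grid (the target voxel
must be an integer multiple of the simulation spacing; block averaging
conserves activity exactly), then adds Gaussian noise with SD =
`noise_sd` × the background level (median of positive voxels), clipped at
zero. Noise is applied in the image domain — the physical
projection-domain statistics are out of scope — and is fully determined by
the seed. Default noise levels: 0.05 for the analog-like arm (FWHM
4.8 mm), 0.03 for the digital-like arm (FWHM 4.2 mm); transverse
resolution is the only system-level physics the comparison quantifies,
with the noise difference standing in for the sensitivity advantage of
digital detectors.

`inject_streaks` emulates metal artifacts as sinusoidal angular streak
patterns (alternating sign, 1/(1+r/r₀) radial decay, r₀ = 30 mm) added to
the pseudo-CT, and a proportional multiplicative bias field applied to the
PET near the metal, emulating the attenuation-correction error. The
amplitude scales with (ρ − 1)/(ρ_steel − 1), so aluminum < titanium <
steel. This is a controlled, reproducible with/without-artifact pair, not
a physical reconstruction model.

`normalize_background` divides by the mean over a background mask so the
mean background SUV is exactly 1; it is idempotent and scale-invariant.
The pipeline derives the mask from the ground truth: inside the phantom
body, at least 10 mm (configurable) from every lesion and from the body
edge.

## Segmentation

* **Ground truth** — Gaussian smoothing (σ = radius/2 voxels, default
  radius 2) followed by 26-connected region growing inside the 50–150 HU
  window on the pseudo-CT.
* **40 % threshold** — T = 0.40 × the ROI maximum; the mask is the
  26-connected component containing the maximum voxel among voxels ≥ T,
  restricted to the ROI dilated by 2 voxels so blur-spread edges are not
  clipped. Ties at T are included. Invariant to global intensity scaling.
* **COA** — T = a·I70 + b·bg with I70 the mean of ROI voxels ≥ 0.70 × the
  maximum and bg the histogram-mode background estimate (voxels outside
  all lesion ROIs and above an air threshold of 5 % of the median positive
  value; 256 histogram bins over the 0.1–99.9 percentile range). The
  published algorithm's threshold function is scanner-calibrated and not
  printed; the linear contrast model with default (a, b) = (0.5, 0.5)
  reproduces its structure, and `calibrate_coa` fits (a, b) on homogeneous
  blurred spheres by Nelder–Mead minimization of the relative volume
  error. A threshold at or above the ROI maximum raises a per-lesion
  empty-mask error; the pipeline records it and continues.

On noise-free blurred homogeneous spheres ≥ 3× FWHM at 10:1 contrast, both
PET methods recover the volume within ±15 %. On inward-hot multilayer
lesions both under-segment — the cold periphery falls below the threshold
set by the hot core — which is the behaviour the volume Bland–Altman
analysis quantifies (strongly negative bias vs ground truth).

A note on recovery coefficients: for the inward-hot two-layer V-series the
*volume* recovery of the 40 % method is largest for the smallest lesion
(blur spreads the hot core over a growing fraction of a shrinking
envelope), so volume-RC is not a monotone PVE measure there. The monotone
partial-volume quantity is the **peak-uptake recovery** (measured maximum
over true core concentration), which rises strictly from V1 to V8; it is
evaluated on the 1 mm blur grid because coarse-grid sampling adds
grid-alignment jitter of a few percent that can locally invert the order.

## Preprocessing and features

Three quantizers map in-mask intensities to levels 1..G:

* **Fixed bin width** (default W = 0.01 SUV), anchored at the in-mask
  minimum — the anchor is not specified in the underlying protocol;
  minimum-anchoring keeps G manageable after background normalization.
  Sensitive to global intensity scaling (G grows with the range).
* **Fixed bin number** (N = 64) — invariant to positive affine maps.
* **Equal-probability quantization** (N = 64, the histogram-equalization
  default) — each distinct value maps through the mid-point of its
  empirical CDF step; the mapping is monotone and purely rank-based, hence
  invariant under any strictly monotone intensity transform, and level
  occupancies are equal up to the largest tie group.

This invariance asymmetry is the mechanism by which different
discretization choices yield different feature reproducibility, and is
machine-checked by the test suite.

The wavelet variant applies a one-level 3D separable DWT (default `sym4`,
a symmetric 8-tap basis; no basis is prescribed by the protocol), scales
the six band-pass sub-bands (those mixing low- and high-pass axes) by 0.5
— the "1:2" weighting relative to LLL/HHH — inverts the transform and
crops to the input shape. With unit weights the round trip is lossless to
1e-8. Filtering runs on the full volume; features are then computed on
in-mask voxels. The equal-probability variant builds its CDF from in-mask
voxels only.

**Matrices.** GLCM and GLRLM accumulate over the 13 unique 3D directions
at distance 1 and merge by summation (symmetric accumulation for GLCM);
runs and pairs truncate at the mask boundary. GLSZM zones are 26-connected
components of equal-level voxels, found via a sparse connectivity graph.
NGTDM uses the 26-neighborhood average restricted to in-mask voxels.
Because the fixed-bin-width quantizer can produce thousands of levels,
matrices are stored in coordinate form with dense accessors; run
percentage is normalized by the 13 merged directions so that a volume of
single-voxel runs yields RP = 1. All matrices and the 40 derived features
are verified against independent brute-force implementations to 1e-10 on
random fixtures.

**Degenerate values** (constant intensities, single-voxel masks,
zero-variance matrices) are flagged in a per-vector degeneracy report
rather than propagated as NaN, and excluded pairwise by the statistics
stage. Kurtosis uses the Pearson convention (normal → 3).

## Statistical decision procedure

For each feature, paired per-lesion values under protocols A and B:

* **Wilcoxon signed-rank** (robust ⇔ two-sided p > α, α = 0.05,
  uncorrected — the robustness criterion is stated uncorrected, and
  leaving it uncorrected is the conservative direction for declaring
  robustness). Zero differences are dropped (classic convention; the
  Pratt variant is available by config). The exact null distribution is
  enumerated over all 2ⁿ sign assignments via midranks for n ≤ 12; larger
  n uses the normal approximation with tie and continuity corrections.
  All-zero differences give p = 1. Differences below 1e-9 relative
  magnitude are treated as zeros: a feature pair that agrees to
  floating-point precision carries no evidence of a protocol effect, and
  a sign test must not react to rounding noise orders of magnitude below
  any measurement noise floor.
* **Spearman** (strongly correlated ⇔ r > 0.8 and p < α/K, with K the
  number of features actually tested, recomputed after degenerate
  exclusions). r is the Pearson correlation of midranks; p is exhaustive
  permutation for n ≤ 8, else the t approximation.
* **Bland–Altman** on dᵢ = 100·(aᵢ − bᵢ)/((aᵢ + bᵢ)/2): comparable ⇔ the
  95 % CI of the mean difference contains zero; the CI uses the t
  distribution because n is small (9–27 lesions). Limits of agreement are
  reported but not part of the comparable criterion.

Features with fewer than 5 valid pairs are reported untestable, never
robust. The cross-factor intersection is the set of features robust under
every factor.

## The four-factor study and the mechanism study

The default study compares: analog-like vs digital-like systems and 2 mm
vs 4 mm voxels on the NEMA phantom (6 spheres segmented at 40 % + 10
background spheres with fixed masks, n = 16); with vs without a steel
insert on both cheese configurations (12 tubes, 40 % segmentation,
including the tube recovery coefficients against the metal-free
reference); and 40 % vs COA on the 27 heterogeneous lesions, with
ground-truth comparisons and the volume Bland–Altman analysis alongside.
Each heterogeneous lesion is simulated in its own warm-background tile —
for a uniform background this is statistically identical to one large
phantom and far cheaper to blur. The full study runs in about a minute on
one CPU at the default problem sizes (1 mm simulation grid, 2 mm output).

The **mechanism study** (`run_scaled_pair_study`) isolates the
discretization mechanism: the 27 lesion images (2 % noise) are extracted
under their ground-truth masks, and arm B is the very same image with
intensities × 1.3 — a voxelwise affine pair. Features invariant to
positive affine (or monotone) intensity maps — skewness, kurtosis,
aucCSH, shape, and every equal-probability feature — come out robust;
fixed-bin-width features shift systematically and are flagged non-robust
yet strongly correlated (the SUV-mean pattern). The co-occurrence
correlation features are a documented borderline class: they are
scale-free by their variance normalization, change only at
quantization-rounding level with no systematic sign, and are therefore
also found robust although they miss the strict 1e-9 invariance bound.

## Known limitations

No sinogram/reconstruction simulation, scatter or randoms; the artifact
model is an emulation; COA is single-pass (no isocontour iteration); the
physical phantoms' exact layer geometries, hole coordinates and 133-name
feature roster are reproduced in structure and count, not verbatim; and
robustness conclusions transfer to real data only to the extent that image
noise, resolution and contrast match the simulated conditions — phantom
results cannot capture physiological variability.
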