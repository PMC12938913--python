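# Methods

## Problem and pipeline

`lbcquant` quantifies stained cell clusters on liquid-based cervical
cytology (LBC) images to discriminate endometrial lesions (atypical
endometrial hyperplasia or endometrial cancer, the *lesion* class) from
benign (*normal*) cases among atypical-glandular-cell cytology. The
pipeline has five stages:

1. **Cluster detection** — the slide image is block-mean downsampled by an
   integer factor (default 3), converted to luminance grayscale
   (0.299 R + 0.587 G + 0.114 B, rounded), and binarized at a fixed global
   threshold (default 210): foreground ⇔ gray < threshold, because stained
   material is dark on a near-white background. Connected foreground
   components (8-connectivity by default, configurable to 4) whose
   downsampled pixel areas lie in [10 000, 100 000 000] inclusive are kept
   as clusters, polygonized and rescaled to full-resolution coordinates.
2. **Feature extraction** — each cluster ROI is resampled to a working
   resolution of 2.00 µm/px (bilinear) and described by GLCM texture,
   LBP, stain-intensity and geometric features (below), restricted to the
   in-polygon pixel mask.
3. **Case aggregation** — one row per case: cluster count plus mean, SD,
   min, max, median, Q75 and Q95 of every cluster feature.
4. **Univariable screening** — per-feature Mann–Whitney ROC AUC against
   the lesion label, oriented to [0.5, 1] with a HIGH/LOW direction, with
   a Youden-index operating point; ranked tables overall and within the
   post-menopausal subgroup.
5. **Multivariable evaluation** — a beam-search wrapper selects a compact
   feature panel and jointly tunes a random forest, inside each training
   fold of a stratified 5-fold CV; performance is estimated only from the
   pooled out-of-fold (OOF) predictions, with a DeLong 95% CI and a
   Youden operating point.

## Feature definitions

**GLCM.** Masked intensities are quantized into `levels` bins (default
32) by uniform binning of [0, 255] (`bin = ⌊v·levels/256⌋`, clipped).
Symmetric co-occurrence counts accumulate over pixel pairs whose both
ends are masked, at unit distance in the four standard directions (0°,
45°, 90°, 135°); each matrix is normalized to sum 1 and features are
averaged over directions with at least one valid pair. The ten features
use the classical definitions: contrast Σ(i−j)²p, homogeneity
Σp/(1+|i−j|), energy Σp², entropy −Σp log₂p, correlation
Σ(i−μ)(j−μ)p/σ² (0 when σ = 0), sum average/variance on p_{x+y},
difference entropy/variance on p_{|x−y|}, and sum-of-squares variance
Σ(i−μ)²p. The **normalized** counterparts first min–max rescale the
masked intensities to [0, 255], which makes them exactly invariant to
affine intensity maps v → a·v + b (a > 0) up to quantization-boundary
ties — they capture contrast *pattern* independent of stain depth.

**LBP.** 8-neighbor local binary patterns at radius 1: bit k (clockwise
from the top-left neighbor, most significant first) is 1 iff that
neighbor ≥ the center; a pixel is eligible when it and all eight
neighbors are masked. Reported are the per-pixel code mean, SD, and the
entropy (bits) of the 256-bin code histogram. A constant region yields
code 255 everywhere (the ≥ comparison sets every bit), hence mean 255,
SD 0, entropy 0.

**Stain/intensity channels.** Per-channel optical density
OD_c = −log₁₀((I_c + ε)/255) with ε = 1e−6·255 guarding log(0).
`od_sum` is OD_R + OD_G + OD_B; `hematoxylin` is the projection of the OD
vector on the unit-normalized hematoxylin vector (0.651, 0.701, 0.290),
and `residual` the Euclidean magnitude of the orthogonal remainder.
Papanicolaou staining has no canonical three-stain OD basis, so the
single-vector-plus-orthogonal-residual decomposition is used; the vector
is configurable. Hue/saturation/brightness follow the hexcone (HSV)
model with hue in [0, 1). Each channel contributes mean, SD (n−1), min,
max and median over the masked pixels. These RGB-derived projections are
descriptive readouts, not stain concentrations — no stain unmixing or
normalization is performed.

**Geometry.** Shoelace polygon area (µm², via mpp²) and perimeter length
(µm). "Length" is the closed-contour perimeter.

## Aggregation and exclusion

Quantiles interpolate linearly between order statistics (the q-th
quantile sits at rank 1 + q(n−1)); SDs use the n−1 denominator. NaN
cluster values are ignored per feature; a column missing in any case is
dropped cohort-wide with a warning, so the analysis matrix is complete.
Cases with fewer than two usable clusters are excluded with reason
`single_cluster` (the SD of one observation is undefined); zero detected
clusters raises an error instead, since it signals a detection failure.
`cluster_count` is itself a candidate feature column, toggleable off.

## Univariable conventions

AUC is the Mann–Whitney probability with ties counted half, computed by
the rank formula (identical to the all-pairs count). Raw AUC < 0.5 is
reported as 1 − AUC with direction LOW; exactly 0.5 is HIGH by convention
and flagged uninformative. Youden candidates are midpoints between
consecutive distinct scores plus one candidate beyond each extreme; a
case is called positive when score ≥ cutoff (HIGH) or ≤ cutoff (LOW).
Ties on J break toward higher specificity, then lower cutoff, and tied
maxima are flagged (they occur routinely with small discrete cohorts).

## Nested selection protocol

Outer CV: stratified 5-fold, shuffled, seeded; fold sizes differ by at
most one per class. Within each outer training fold the beam search
scores every candidate (subset, grid point) by the **mean inner-CV AUC**
of the fitted forest (stratified 3-fold by default inside the training
fold), keeps the best `beam_width` subsets per size, and extends them one
feature at a time to `max_subset_size`; the winner over all sizes is
refit on the whole training fold and scores the held-out cases. Ties
break toward smaller subsets, then lexicographic feature names. Class
weights are inverse to class frequencies. Forest randomness is seeded
deterministically from (config seed, fold, subset, grid point), so the
whole evaluation is bit-reproducible.

Default grid: trees ∈ {250, 500, 1000}; mtry ∈ {1, ⌈√p⌉, ⌈p/2⌉};
minimal node size ∈ {1, 5, 10}; split rule ∈ {impurity (gini),
random-threshold splits}; beam width 5; max panel size 8. These bracket
the compact 3–5-feature panels such analyses typically lock.
`SearchConfig.fast()` (beam 2, panel ≤ 2, one grid point of 60 trees,
inner 2-fold) is the reduced configuration used for repeated simulation
studies; wrappers of this kind converge to the same qualitative behavior
while keeping a 50-replicate null study tractable on one core.

`panel_mode="locked"` selects a single panel on the full matrix before
fold splitting and then cross-validates it. This mirrors reporting a
fixed panel, but it leaks selection information into the CV estimate; the
default `per-fold` mode is the strict, leakage-free reading, and the test
suite measures the locked mode's optimism explicitly (null mean OOF AUC
> 0.6 versus ≈ 0.5 for per-fold).

**DeLong CI.** Placement-value (structural-components) variance of the
Mann–Whitney AUC; CI = AUC ± z₀.₉₇₅·SE clipped to [0, 1]. Perfect
separation has zero estimated variance and yields a degenerate interval
with a warning. The DeLong point estimate equals `roc_auc` exactly.

## Synthetic cohorts

Real AGC slide cohorts are institutional and not deposited, so the
package generates its own study material in two forms.

*Image cohorts* (`generate_cohort`): near-white background (gray 250)
with elliptical hematoxylin-toned blobs (base RGB (82, 60, 128), radii
24–72 px at 2/3 µm/px so a one-third downsample lands on the 2.00 µm/px
working resolution). Each cluster draws a per-pixel Gaussian noise SD
σ ~ N(11, 3) (normal class) shifted by `effect_size`·3 in the lesion
class — the dispersion parameter — plus a block-replicated low-frequency
shading field with amplitude a ~ N(10, 3) shifted by `texture_effect`·3,
emulating texture heterogeneity. Overlapping blobs merge, as connected
stained material does. Per-class menopause flags are assigned at a fixed
fraction (default 0.5).

*Feature matrices* (`generate_feature_matrix`): standard-normal columns
with the first `n_informative` shifted by `effect_size` in the lesion
class, giving a closed-form single-feature AUC Φ(d/√2) — the fast route
for calibrating the statistical machinery.

The generator reproduces the *statistical structure* the analysis
assumes — class differences concentrated in dispersion-type features,
exchangeable noise features, merged-cluster geometry — but not real
cytomorphology: no nuclei, no three-dimensional cluster architecture, no
staining batch effects, no platform differences (SurePath vs ThinPrep),
and cluster counts/sizes far below clinical slides for tractability.
Passing tests therefore demonstrate that the *computational procedure* is
correct and leakage-free, not that the clinical effect sizes transfer.

## Numerical choices and degeneracies

- Entropies in bits; 0·log 0 := 0. GLCM correlation at zero marginal SD
  is 0. SD of one observation is 0 at the cluster level (and triggers
  case exclusion at the case level).
- Downsampling crops incomplete edge tiles before block averaging.
- Component polygons are traced along pixel corners, so the polygon's
  shoelace area equals the component pixel count exactly (holes ignored;
  corner pinches at diagonal contacts resolve by preferring the rightmost
  turn, keeping loops non-crossing). Rescaling multiplies vertices by the
  downsample factor; full-resolution areas are recomputed from the
  rescaled polygon.
- ROI masks come from polygon rasterization at patch resolution; a
  degenerate polygon smaller than one patch pixel gets its center pixel
  forced in.
- Detection parameters for synthetic images use a lower minimum area
  (tens of downsampled pixels) than the full-scale default, matching the
  smaller synthetic blobs; the threshold (210) and the rest of the chain
  are unchanged.

## Problem sizes in the shipped studies

The test-suite and acceptance-script studies use: 8×8 patches for the
texture oracles (50 replicates), 64×64 masks for the detection oracle,
1000 simulated 30+30 cohorts for DeLong coverage, 50 (tests) / 12
(script) seeds of 50-feature 30+30 null matrices for the leakage guard
with the reduced search configuration, 200-case matrices for signal
recovery, and 40-case (tests) / 24-case (script) 500×500-px image cohorts
for the end-to-end run. These sizes were chosen so the complete studies
run comfortably on a single core while leaving the measured properties
(exactness, coverage, calibration) unambiguous.

## Known limitations

- Single-vector stain model; no color deconvolution with a fitted basis.
- Only the outer contour of a component is kept; clusters with true
  lumina are measured including the hole area in geometry.
- The beam search treats the inner mean AUC as the sole criterion; no
  parsimony penalty beyond the tie-break.
- Subgroup (post-menopausal) analysis is univariable only; nested CV in
  small subgroups is unstable and deliberately not offered by default.
- GLCM parameters (32 levels, distance 1, four averaged angles) follow
  common texture-analysis practice and are exposed in `GLCMParams`; other
  toolchains may bin or average differently, so absolute feature values
  are comparable only within a fixed configuration.
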