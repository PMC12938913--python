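"""Synthetic two-class cytology cohorts.

The institutional SurePath/ThinPrep slide cohorts behind this kind of
analysis are not publicly deposited, so this module generates stand-in
cohorts with the statistical structure the downstream analysis assumes:
two classes of cases (``normal`` vs ``lesion``, the AEH/EC-positive class)
whose separation is concentrated in *dispersion-type* measurements —
within-cluster intensity spread and texture heterogeneity — mirroring the
finding that standard-deviation-style stain features rank highest in
univariable screening of real cohorts.

Two generators are provided:

* :func:`generate_cohort` renders raster images of hematoxylin-toned cell
  clusters on a near-white background, for exercising the full image
  pipeline (detection → feature extraction → aggregation → modeling).
* :func:`generate_feature_matrix` emits case-level Gaussian feature tables
  directly, for fast statistical tests of the modeling stages.

Both are bit-reproducible for a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "SlideCase", "generate_cohort", "generate_feature_matrix"]

#: Hematoxylin-like base color (RGB) used for cluster interiors.
HEMATOXYLIN_RGB = (82.0, 60.0, 128.0)

#: Background gray level (near-white, above any plausible stain threshold).
BACKGROUND_GRAY = 250


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    Parameters
    ----------
    n_normal, n_lesion
        Number of cases per class.
    clusters_per_case
        Inclusive ``(lo, hi)`` range for the per-case cluster count.
    effect_size
        Cohen's d shift (unitless) applied to the lesion class's
        within-cluster intensity-dispersion parameter.
    texture_effect
        Analogous standardized shift applied to the amplitude of the
        low-frequency texture pattern inside lesion-class clusters.
    mpp
        Microns per pixel of the generated full-resolution images.  The
        default of 2/3 µm/px means a one-third downsample lands exactly on
        the 2.00 µm/px working resolution of the feature extractor.
    seed
        RNG seed; identical spec + seed reproduces identical output.
    menopause_fraction
        Fraction of cases per class flagged post-menopausal.
    image_shape
        (height, width) of each full-resolution image in pixels.
    """

    n_normal: int
    n_lesion: int
    clusters_per_case: tuple[int, int] = (4, 12)
    effect_size: float = 0.0
    texture_effect: float = 0.0
    mpp: float = 2.0 / 3.0
    seed: int = 0
    menopause_fraction: float = 0.5
    image_shape: tuple[int, int] = (600, 600)

    def validate(self) -> None:
        if self.n_normal < 0:
            raise ValueError("n_normal must be >= 0")
        if self.n_lesion < 0:
            raise ValueError("n_lesion must be >= 0")
        lo, hi = self.clusters_per_case
        if lo < 1 or hi < lo:
            raise ValueError("clusters_per_case must satisfy 1 <= lo <= hi")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        if not 0.0 <= self.menopause_fraction <= 1.0:
            raise ValueError("menopause_fraction must be in [0, 1]")


@dataclass
class SlideCase:
    """One case: an RGB image with calibration, label and menopause flag."""

    case_id: str
    image: np.ndarray  # (H, W, 3) uint8
    mpp: float
    label: str  # "normal" | "lesion"
    menopause: bool

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError(f"case {self.case_id}: mpp must be > 0")
        if self.label not in ("normal", "lesion"):
            raise ValueError(f"case {self.case_id}: label must be normal|lesion")


# dispersion model: per-cluster pixel-noise SD sigma ~ N(SIGMA_MEAN, SIGMA_SD),
# shifted by effect_size * SIGMA_SD in the lesion class; truncated at SIGMA_MIN.
SIGMA_MEAN = 11.0
SIGMA_SD = 3.0
SIGMA_MIN = 1.0

# texture model: low-frequency multiplicative shading with per-cluster
# amplitude a ~ N(TEX_MEAN, TEX_SD), shifted by texture_effect * TEX_SD.
TEX_MEAN = 10.0
TEX_SD = 3.0
TEX_BLOCK = 8  # coarse-noise block size (full-resolution pixels)


def _menopause_flags(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def _render_case(
    rng: np.random.Generator, spec: CohortSpec, is_lesion: bool
) -> np.ndarray:
    h, w = spec.image_shape
    img = np.full((h, w, 3), BACKGROUND_GRAY, dtype=np.float64)

    lo, hi = spec.clusters_per_case
    n_clusters = int(rng.integers(lo, hi + 1))
    d_sigma = spec.effect_size if is_lesion else 0.0
    d_tex = spec.texture_effect if is_lesion else 0.0

    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_clusters):
        ry = rng.uniform(24.0, 72.0)
        rx = rng.uniform(24.0, 72.0)
        cy = rng.uniform(ry, h - ry)
        cx = rng.uniform(rx, w - rx)
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

        sigma = max(SIGMA_MIN, rng.normal(SIGMA_MEAN + d_sigma * SIGMA_SD, SIGMA_SD))
        amp = max(0.0, rng.normal(TEX_MEAN + d_tex * TEX_SD, TEX_SD))

        # coarse multiplicative shading, upsampled by block replication
        gh = h // TEX_BLOCK + 1
        gw = w // TEX_BLOCK + 1
        coarse = rng.normal(0.0, 1.0, size=(gh, gw))
        shading = np.kron(coarse, np.ones((TEX_BLOCK, TEX_BLOCK)))[:h, :w]

        noise = rng.normal(0.0, sigma, size=(h, w))
        for c, base in enumerate(HEMATOXYLIN_RGB):
            vals = base + noise + amp * shading
            img[..., c] = np.where(inside, vals, img[..., c])

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_cohort(spec: CohortSpec) -> list[SlideCase]:
    """Generate a synthetic cohort of slide cases.

    Each case image is a near-white background carrying elliptical
    hematoxylin-toned cluster blobs; overlapping blobs merge, as connected
    components of real stained material do.  The lesion class draws its
    per-cluster pixel-noise SD (and texture amplitude) from distributions
    shifted by ``effect_size`` (``texture_effect``) standard deviations.

    Returns the normal cases followed by the lesion cases, with stable
    ``case_id``s ``N000…``/``L000…``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    meno_n = _menopause_flags(spec.n_normal, spec.menopause_fraction, rng)
    meno_l = _menopause_flags(spec.n_lesion, spec.menopause_fraction, rng)

    cases: list[SlideCase] = []
    for i in range(spec.n_normal):
        img = _render_case(rng, spec, is_lesion=False)
        cases.append(SlideCase(f"N{i:03d}", img, spec.mpp, "normal", bool(meno_n[i])))
    for i in range(spec.n_lesion):
        img = _render_case(rng, spec, is_lesion=True)
        cases.append(SlideCase(f"L{i:03d}", img, spec.mpp, "lesion", bool(meno_l[i])))
    return cases


def generate_feature_matrix(
    spec: CohortSpec, n_features: int, n_informative: int
) -> pd.DataFrame:
    """Generate a case-level feature table directly (no rasterization).

    Columns are standard-normal per class; the first ``n_informative``
    columns are shifted upward by ``effect_size`` in the lesion class, so a
    single informative column has population AUC Φ(d/√2).  The remaining
    columns are exchangeable between classes.

    Returns a DataFrame indexed by ``case_id`` with columns ``label``
    (0 = normal, 1 = lesion), ``menopause`` and ``f000`` … ``f{n-1}``.
    """
    spec.validate()
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    rng = np.random.default_rng(spec.seed)

    n = spec.n_normal + spec.n_lesion
    labels = np.r_[np.zeros(spec.n_normal, dtype=int), np.ones(spec.n_lesion, dtype=int)]
    x = rng.normal(0.0, 1.0, size=(n, n_features))
    x[labels == 1, :n_informative] += spec.effect_size

    meno = np.r_[
        _menopause_flags(spec.n_normal, spec.menopause_fraction, rng),
        _menopause_flags(spec.n_lesion, spec.menopause_fraction, rng),
    ]
    case_ids = [f"N{i:03d}" for i in range(spec.n_normal)] + [
        f"L{i:03d}" for i in range(spec.n_lesion)
    ]
    df = pd.DataFrame(
        x, columns=[f"f{j:03d}" for j in range(n_features)], index=pd.Index(case_ids, name="case_id")
    )
    df.insert(0, "label", labels)
    df.insert(1, "menopause", meno)
    return df
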