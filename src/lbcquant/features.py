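"""Per-cluster feature extraction.

Each detected cluster is resampled to a fixed working resolution
(2.00 µm/px by default) and described by:

* Haralick gray-level co-occurrence matrix (GLCM) texture features —
  correlation, contrast, homogeneity, energy, entropy, difference
  entropy/variance, sum average, sum variance, sum-of-squares variance —
  plus *normalized* counterparts computed after min–max rescaling the
  region's intensities to [0, 255], which makes them invariant to affine
  intensity changes;
* local binary pattern (LBP) code statistics (mean, SD, entropy);
* intensity statistics (mean, SD, min, max, median) over nine per-pixel
  channels: optical-density sum, hematoxylin projection, residual
  (orthogonal OD remainder), R, G, B, hue, saturation, brightness;
* geometric descriptors (area in µm², perimeter length in µm).

All texture/intensity computations honor the in-polygon mask: only masked
pixels (and, for the GLCM, pixel pairs with both ends masked) contribute.
Degenerate regions yield NaN feature values, which downstream aggregation
treats as absent.

Entropies are in bits (log base 2, with 0·log 0 := 0); standard deviations
use the n−1 denominator; GLCM correlation on a constant region is 0 by
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize
from shapely.geometry import Polygon as ShapelyPolygon

__all__ = [
    "GLCMParams",
    "GLCM_FEATURE_NAMES",
    "INTENSITY_CHANNELS",
    "resample_roi",
    "glcm_features",
    "glcm_features_normalized",
    "lbp_codes",
    "lbp_features",
    "stain_channels",
    "intensity_stats",
    "geometry_features",
    "extract_cluster_features",
]

GLCM_FEATURE_NAMES = (
    "correlation",
    "contrast",
    "homogeneity",
    "energy",
    "entropy",
    "difference_entropy",
    "difference_variance",
    "sum_average",
    "sum_variance",
    "sum_of_squares_variance",
)

INTENSITY_CHANNELS = (
    "od_sum",
    "hematoxylin",
    "residual",
    "red",
    "green",
    "blue",
    "hue",
    "saturation",
    "brightness",
)

STAT_NAMES = ("mean", "sd", "min", "max", "median")

#: Hematoxylin stain vector in optical-density space (normalized on use).
HEMATOXYLIN_OD_VECTOR = (0.651, 0.701, 0.290)

# offsets (dy, dx) for angles 0°, 45°, 90°, 135° at unit distance
_ANGLE_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class GLCMParams:
    """GLCM computation parameters.

    ``levels`` gray bins by uniform binning of [0, 255]; symmetric
    co-occurrence at ``distance`` in each of the four standard angles,
    features averaged over angles.
    """

    levels: int = 32
    distance: int = 1
    angles: tuple[tuple[int, int], ...] = _ANGLE_OFFSETS

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


def _nan_features(names) -> dict[str, float]:
    return {n: float("nan") for n in names}


def _quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Uniform binning of [0, 255] into ``levels`` bins."""
    q = np.floor(values.astype(np.float64) * levels / 256.0).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _glcm_matrix(
    quant: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int
) -> np.ndarray | None:
    """Symmetric co-occurrence matrix for one offset, or None if no pair."""
    dy, dx = offset
    h, w = quant.shape
    y0, y1 = max(0, -dy), min(h, h - dy)
    x0, x1 = max(0, -dx), min(w, w - dx)
    if y0 >= y1 or x0 >= x1:
        return None
    a = quant[y0:y1, x0:x1]
    b = quant[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    valid = mask[y0:y1, x0:x1] & mask[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    if not valid.any():
        return None
    ai, bi = a[valid], b[valid]
    counts = np.bincount(ai * levels + bi, minlength=levels * levels).astype(np.float64)
    m = counts.reshape(levels, levels)
    m = m + m.T  # symmetric
    return m / m.sum()


def _haralick(p: np.ndarray) -> dict[str, float]:
    """The ten Haralick-style features of one normalized GLCM."""
    levels = p.shape[0]
    idx = np.arange(levels, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    px = p.sum(axis=1)  # marginal (symmetric: px == py)

    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    mu = float((idx * px).sum())
    var = float((((idx - mu) ** 2) * px).sum())
    sigma = math.sqrt(var)
    if sigma < 1e-12:
        correlation = 0.0
    else:
        correlation = float((((i - mu) * (j - mu) * p).sum()) / (sigma * sigma))

    # sum / difference distributions
    k_sum = np.arange(2 * levels - 1, dtype=np.float64)
    p_sum = np.zeros(2 * levels - 1)
    k_diff = np.arange(levels, dtype=np.float64)
    p_diff = np.zeros(levels)
    ii, jj = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_of_squares_variance = float((((i - mu) ** 2) * p).sum())

    nzd = p_diff[p_diff > 0]
    difference_entropy = float(-(nzd * np.log2(nzd)).sum())
    mu_d = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - mu_d) ** 2 * p_diff).sum())

    return {
        "correlation": correlation,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "energy": energy,
        "entropy": entropy,
        "difference_entropy": difference_entropy,
        "difference_variance": difference_variance,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_of_squares_variance": sum_of_squares_variance,
    }


def glcm_features(
    patch_gray: np.ndarray,
    mask: np.ndarray | None = None,
    params: GLCMParams = GLCMParams(),
) -> dict[str, float]:
    """Masked Haralick GLCM features, averaged over the configured angles.

    Intensities are quantized by uniform binning of [0, 255] into
    ``params.levels`` bins; only pixel pairs with both ends inside the
    mask contribute.  Returns NaN for every feature when no angle has a
    valid co-occurring pair.
    """
    if mask is None:
        mask = np.ones(patch_gray.shape, dtype=bool)
    quant = _quantize(np.asarray(patch_gray), params.levels)
    d = params.distance
    per_angle = []
    for dy, dx in params.angles:
        m = _glcm_matrix(quant, mask, (dy * d, dx * d), params.levels)
        if m is not None:
            per_angle.append(_haralick(m))
    if not per_angle:
        return _nan_features(GLCM_FEATURE_NAMES)
    return {
        name: float(np.mean([f[name] for f in per_angle]))
        for name in GLCM_FEATURE_NAMES
    }


def glcm_features_normalized(
    patch_gray: np.ndarray,
    mask: np.ndarray | None = None,
    params: GLCMParams = GLCMParams(),
) -> dict[str, float]:
    """GLCM features after min–max rescaling masked intensities to [0, 255].

    The rescale makes the outputs invariant to affine intensity maps
    v → a·v + b (a > 0).  A constant region degenerates exactly as the raw
    path does.  Keys are prefixed ``normalized_``.
    """
    if mask is None:
        mask = np.ones(patch_gray.shape, dtype=bool)
    vals = np.asarray(patch_gray, dtype=np.float64)
    if not mask.any():
        return {f"normalized_{n}": float("nan") for n in GLCM_FEATURE_NAMES}
    lo = vals[mask].min()
    hi = vals[mask].max()
    if hi > lo:
        scaled = (vals - lo) * (255.0 / (hi - lo))
    else:
        scaled = np.zeros_like(vals)
    raw = glcm_features(scaled, mask, params)
    return {f"normalized_{n}": v for n, v in raw.items()}


# clockwise from top-left; bit k carries weight 2**(7-k)
_LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_codes(patch_gray: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel 8-neighbor LBP codes at radius 1, raster order.

    A pixel is eligible when it and all eight neighbors are masked and
    in-bounds; bit k (clockwise from the top-left neighbor, most
    significant first) is 1 iff that neighbor >= the center.  Returns the
    codes of eligible pixels only.
    """
    gray = np.asarray(patch_gray, dtype=np.float64)
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    h, w = gray.shape
    if h < 3 or w < 3:
        return np.empty(0, dtype=np.int64)

    center = gray[1:-1, 1:-1]
    eligible = mask[1:-1, 1:-1].copy()
    codes = np.zeros(center.shape, dtype=np.int64)
    for k, (dy, dx) in enumerate(_LBP_OFFSETS):
        nb = gray[1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]
        nb_mask = mask[1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]
        eligible &= nb_mask
        codes |= (nb >= center).astype(np.int64) << (7 - k)
    return codes[eligible]


def lbp_features(
    patch_gray: np.ndarray, mask: np.ndarray | None = None
) -> dict[str, float]:
    """LBP code statistics: mean, SD (n−1), and 256-bin histogram entropy
    in bits; NaN if no pixel is eligible (see :func:`lbp_codes`)."""
    vals = lbp_codes(patch_gray, mask)
    if vals.size == 0:
        return _nan_features(("lbp_mean", "lbp_sd", "lbp_entropy"))
    hist = np.bincount(vals, minlength=256).astype(np.float64)
    p = hist / hist.sum()
    nz = p[p > 0]
    return {
        "lbp_mean": float(vals.mean()),
        "lbp_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "lbp_entropy": float(-(nz * np.log2(nz)).sum()),
    }


def stain_channels(
    patch_rgb: np.ndarray,
    hematoxylin_vector: tuple[float, float, float] = HEMATOXYLIN_OD_VECTOR,
) -> dict[str, np.ndarray]:
    """Per-pixel channel images used for intensity statistics.

    Optical density per channel is OD_c = −log10((I_c + ε)/255) with a
    small ε guard against log(0); ``hematoxylin`` is the projection of the
    OD vector onto the (unit-normalized) hematoxylin stain vector and
    ``residual`` the Euclidean magnitude of the orthogonal remainder.
    Hue/saturation/brightness follow the standard hexcone (HSV) model with
    hue in [0, 1).
    """
    rgb = np.asarray(patch_rgb, dtype=np.float64)
    eps = 1e-6 * 255.0
    od = -np.log10((rgb + eps) / 255.0)
    hvec = np.asarray(hematoxylin_vector, dtype=np.float64)
    hvec = hvec / np.linalg.norm(hvec)
    hema = od @ hvec
    residual = np.linalg.norm(od - hema[..., None] * hvec, axis=-1)
    hsv = rgb2hsv(np.clip(rgb, 0, 255) / 255.0)
    return {
        "od_sum": od.sum(axis=-1),
        "hematoxylin": hema,
        "residual": residual,
        "red": rgb[..., 0],
        "green": rgb[..., 1],
        "blue": rgb[..., 2],
        "hue": hsv[..., 0],
        "saturation": hsv[..., 1],
        "brightness": hsv[..., 2],
    }


def intensity_stats(values: np.ndarray) -> dict[str, float]:
    """mean/SD/min/max/median of a value vector; SD 0 for a single value."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        return _nan_features(STAT_NAMES)
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "median": float(np.median(v)),
    }


def geometry_features(annotation, mpp: float) -> dict[str, float]:
    """Polygon area (µm²) and perimeter length (µm) of an annotation."""
    poly = np.asarray(annotation.polygon, dtype=np.float64)
    if poly.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    shp = ShapelyPolygon(poly)
    return {"area_um2": shp.area * mpp**2, "length_um": shp.length * mpp}


def resample_roi(
    case, annotation, target_mpp: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Crop the annotation's bounding box and rescale to ``target_mpp``.

    Returns the bilinear-resampled RGB patch (float64, 0–255 scale) and a
    boolean in-polygon mask at patch resolution.  A polygon so small that
    no patch pixel falls inside gets its center pixel forced in.
    """
    poly = np.asarray(annotation.polygon, dtype=np.float64)
    h, w = case.image.shape[:2]
    x0, y0 = np.floor(poly.min(axis=0)).astype(int)
    x1, y1 = np.ceil(poly.max(axis=0)).astype(int)
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"annotation {annotation.cluster_id} outside image bounds")
    x1, y1 = max(x1, x0 + 1), max(y1, y0 + 1)

    crop = case.image[y0:y1, x0:x1].astype(np.float64)
    scale = case.mpp / target_mpp
    oh = max(1, int(round(crop.shape[0] * scale)))
    ow = max(1, int(round(crop.shape[1] * scale)))
    if (oh, ow) == crop.shape[:2]:
        patch = crop
    else:
        patch = resize(
            crop, (oh, ow), order=1, preserve_range=True, anti_aliasing=False
        )

    sy = oh / crop.shape[0]
    sx = ow / crop.shape[1]
    rr, cc = draw_polygon(
        (poly[:, 1] - y0) * sy, (poly[:, 0] - x0) * sx, shape=(oh, ow)
    )
    mask = np.zeros((oh, ow), dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        mask[oh // 2, ow // 2] = True
    return patch, mask


def extract_cluster_features(
    case,
    annotation,
    glcm_params: GLCMParams = GLCMParams(),
    target_mpp: float = 2.0,
) -> dict[str, float]:
    """All per-cluster features as a flat name → value map.

    Intensity statistics are named ``<channel>_<stat>`` (e.g.
    ``hematoxylin_sd``); GLCM features carry their Haralick names with a
    ``normalized_`` prefix for the min–max-rescaled variants.
    """
    patch, mask = resample_roi(case, annotation, target_mpp)
    gray = 0.299 * patch[..., 0] + 0.587 * patch[..., 1] + 0.114 * patch[..., 2]

    out: dict[str, float] = {}
    out.update(glcm_features(gray, mask, glcm_params))
    out.update(glcm_features_normalized(gray, mask, glcm_params))
    out.update(lbp_features(gray, mask))
    channels = stain_channels(patch)
    for name, img in channels.items():
        stats = intensity_stats(img[mask])
        for stat, value in stats.items():
            out[f"{name}_{stat}"] = value
    out.update(geometry_features(annotation, case.mpp))
    return out
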