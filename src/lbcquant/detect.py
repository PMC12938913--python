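"""Cell-cluster detection on slide images.

Stained cell clusters sit dark on a near-white liquid-based-cytology
background, so detection is deliberately simple and fully reproducible:
the image is downsampled, converted to grayscale, binarized at a fixed
global threshold (default 210), connected foreground components are
extracted and filtered by pixel area, and each surviving component's outer
boundary is polygonized and rescaled to full-resolution coordinates.

Polygons are traced along pixel *corners*, so the shoelace area of a traced
polygon equals the component's pixel count exactly (minus any interior
holes, which are ignored: only the outer contour is kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectionParams",
    "ClusterAnnotation",
    "CalibrationError",
    "downsample",
    "to_grayscale",
    "binarize",
    "extract_regions",
    "filter_by_area",
    "detect_clusters",
]


class CalibrationError(ValueError):
    """Raised when a case lacks a usable microns-per-pixel calibration."""


@dataclass(frozen=True)
class DetectionParams:
    """Detection parameters.

    Defaults follow the standard workflow: one-third-resolution scan,
    fixed gray threshold 210, and retention of components with downsampled
    areas between 10,000 and 100,000,000 pixels inclusive.
    """

    downsample_factor: int = 3
    gray_threshold: int = 210
    min_area_px: float = 10_000
    max_area_px: float = 100_000_000
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.gray_threshold < 255:
            raise ValueError("gray_threshold must be in (0, 255)")
        if not 0 < self.min_area_px < self.max_area_px:
            raise ValueError("need 0 < min_area_px < max_area_px")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ClusterAnnotation:
    """A detected cluster: polygon in full-resolution pixel coordinates.

    ``polygon`` is a closed ring stored without the repeated first vertex,
    x rightward, y downward, 0-based.  ``area_px`` is the shoelace area of
    the full-resolution polygon; ``area_um2 = area_px * mpp**2``.
    """

    cluster_id: str
    polygon: np.ndarray  # (n, 2) float, columns (x, y)
    area_px: float
    area_um2: float
    excluded: bool = False


def downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample by an integer factor (per channel).

    Incomplete edge tiles are cropped.  ``factor=1`` returns the input.
    """
    if factor == 1:
        return image
    h, w = image.shape[:2]
    hh, ww = (h // factor) * factor, (w // factor) * factor
    img = image[:hh, :ww].astype(np.float64)
    if img.ndim == 2:
        img = img.reshape(hh // factor, factor, ww // factor, factor)
        out = img.mean(axis=(1, 3))
    else:
        img = img.reshape(hh // factor, factor, ww // factor, factor, -1)
        out = img.mean(axis=(1, 3))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale: round(0.299 R + 0.587 G + 0.114 B)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    rgb = image.astype(np.float64)
    gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def binarize(gray: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground = pixels strictly darker than the threshold."""
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    return gray < threshold


_DIRS = {(1, 0): 0, (0, 1): 1, (-1, 0): 2, (0, -1): 3}
_DIRLIST = [(1, 0), (0, 1), (-1, 0), (0, -1)]  # +x, +y, -x, -y


def _trace_outer_polygon(mask: np.ndarray) -> np.ndarray:
    """Outer boundary polygon of a connected boolean mask.

    Edges run along pixel corners with the interior kept to the right of
    the walking direction; the loop with the largest shoelace area is the
    outer contour.  Corners shared by diagonally touching pixels are
    resolved by preferring the rightmost turn, so loops never cross.
    """
    padded = np.pad(mask, 1)
    # boundary edges: for each fg pixel, one directed edge per exposed side
    ys, xs = np.nonzero(padded)
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a: tuple[int, int], b: tuple[int, int]) -> None:
        edges.setdefault(a, []).append(b)

    for y, x in zip(ys.tolist(), xs.tolist()):
        if not padded[y - 1, x]:  # bg above: go +x along top
            add((x, y), (x + 1, y))
        if not padded[y + 1, x]:  # bg below: go -x along bottom
            add((x + 1, y + 1), (x, y + 1))
        if not padded[y, x - 1]:  # bg left: go -y along left side
            add((x, y + 1), (x, y))
        if not padded[y, x + 1]:  # bg right: go +y along right side
            add((x + 1, y), (x + 1, y + 1))

    for v in edges.values():
        v.sort()

    loops: list[np.ndarray] = []
    while edges:
        start = min(edges)
        loop = [start]
        prev_dir: tuple[int, int] | None = None
        cur = start
        while True:
            outs = edges[cur]
            if len(outs) == 1 or prev_dir is None:
                nxt = outs.pop(0)
            else:
                # prefer right turn, then straight, then left
                di = _DIRS[prev_dir]
                order = [_DIRLIST[(di + 1) % 4], prev_dir, _DIRLIST[(di - 1) % 4]]
                for d in order:
                    cand = (cur[0] + d[0], cur[1] + d[1])
                    if cand in outs:
                        nxt = cand
                        outs.remove(cand)
                        break
                else:  # pragma: no cover - cannot happen on valid masks
                    nxt = outs.pop(0)
            if not outs:
                del edges[cur]
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            if nxt == start:
                break
            loop.append(nxt)
            cur = nxt
        loops.append(np.asarray(loop, dtype=np.float64))

    def shoelace(p: np.ndarray) -> float:
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))

    outer = max(loops, key=shoelace)
    outer = outer - 1.0  # undo padding offset

    # collapse collinear runs
    d = np.diff(np.vstack([outer, outer[:1]]), axis=0)
    keep = np.any(d != np.roll(d, 1, axis=0), axis=1)
    return outer[keep]


def polygon_area(polygon: np.ndarray) -> float:
    """Shoelace area (absolute) of a closed ring stored open."""
    x, y = polygon[:, 0], polygon[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def extract_regions(
    mask: np.ndarray, params: DetectionParams
) -> list[tuple[np.ndarray, int]]:
    """Connected foreground components as (outer polygon, pixel area).

    Components are sorted by descending area; ties broken by the
    topmost-then-leftmost pixel in scan order.  Holes are ignored (outer
    contour only).  Coordinates are in the mask's own (downsampled) frame.
    """
    structure = (
        np.ones((3, 3), dtype=int)
        if params.connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []
    areas = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1)).astype(int)
    # seed pixel = first in row-major scan order, per label
    flat = labeled.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    # reversed so earliest index wins
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(1, n + 1), key=lambda lb: (-areas[lb - 1], first_idx[lb]))

    slices = ndimage.find_objects(labeled)
    out: list[tuple[np.ndarray, int]] = []
    for lb in order:
        sl = slices[lb - 1]
        sub = labeled[sl] == lb
        poly = _trace_outer_polygon(sub)
        poly[:, 0] += sl[1].start
        poly[:, 1] += sl[0].start
        out.append((poly, int(areas[lb - 1])))
    return out


def filter_by_area(
    regions: list[tuple[np.ndarray, int]], params: DetectionParams
) -> list[tuple[np.ndarray, int]]:
    """Keep regions with min_area_px <= area <= max_area_px (inclusive)."""
    return [r for r in regions if params.min_area_px <= r[1] <= params.max_area_px]


def detect_clusters(
    case,
    params: DetectionParams = DetectionParams(),
    exclusion_mask: np.ndarray | None = None,
) -> list[ClusterAnnotation]:
    """Detect cell clusters on a case image.

    Composes downsample → grayscale → binarize → component extraction →
    area filter, then rescales polygons to full-resolution coordinates and
    recomputes areas from the rescaled polygons.  Annotations with any
    vertex inside ``exclusion_mask`` (a full-resolution boolean raster, the
    stand-in for manual exclusion of non-cluster material) are flagged
    ``excluded=True`` rather than dropped.
    """
    mpp = getattr(case, "mpp", None)
    if mpp is None or not mpp > 0:
        raise CalibrationError(f"case {getattr(case, 'case_id', '?')}: mpp missing")

    small = downsample(case.image, params.downsample_factor)
    gray = to_grayscale(small)
    mask = binarize(gray, params.gray_threshold)
    regions = filter_by_area(extract_regions(mask, params), params)

    annotations: list[ClusterAnnotation] = []
    f = float(params.downsample_factor)
    for i, (poly, _area_ds) in enumerate(regions):
        full = poly * f
        area_px = polygon_area(full)
        excluded = False
        if exclusion_mask is not None:
            h, w = exclusion_mask.shape
            xs = np.clip(full[:, 0].astype(int), 0, w - 1)
            ys = np.clip(full[:, 1].astype(int), 0, h - 1)
            excluded = bool(exclusion_mask[ys, xs].any())
        annotations.append(
            ClusterAnnotation(
                cluster_id=f"{case.case_id}_c{i:04d}",
                polygon=full,
                area_px=area_px,
                area_um2=area_px * mpp**2,
                excluded=excluded,
            )
        )
    return annotations
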