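"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use plain Python loops and textbook
definitions so they share no code path with the vectorized implementations
they check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


# ---------------------------------------------------------------- GLCM oracle


def oracle_quantize(v: float, levels: int) -> int:
    q = int(math.floor(v * levels / 256.0))
    return min(max(q, 0), levels - 1)


def oracle_glcm_features(patch, mask, levels=32, distance=1):
    """Haralick features by explicit pair enumeration, averaged over the
    four standard angles; NaN when no angle yields a valid pair."""
    h, w = patch.shape
    offsets = [(0, distance), (-distance, distance), (-distance, 0), (-distance, -distance)]
    per_angle = []
    for dy, dx in offsets:
        counts: dict[tuple[int, int], float] = {}
        total = 0.0
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if not (0 <= y2 < h and 0 <= x2 < w):
                    continue
                if not (mask[y, x] and mask[y2, x2]):
                    continue
                a = oracle_quantize(float(patch[y, x]), levels)
                b = oracle_quantize(float(patch[y2, x2]), levels)
                counts[(a, b)] = counts.get((a, b), 0.0) + 1.0
                counts[(b, a)] = counts.get((b, a), 0.0) + 1.0
                total += 2.0
        if total == 0:
            continue
        p = {k: v / total for k, v in counts.items()}
        per_angle.append(_oracle_haralick(p, levels))
    if not per_angle:
        return None
    return {k: sum(f[k] for f in per_angle) / len(per_angle) for k in per_angle[0]}


def _oracle_haralick(p: dict[tuple[int, int], float], levels: int) -> dict[str, float]:
    px = [0.0] * levels
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(i * px[i] for i in range(levels))
    var = sum((i - mu) ** 2 * px[i] for i in range(levels))
    sigma = math.sqrt(var)

    contrast = sum((i - j) ** 2 * v for (i, j), v in p.items())
    homogeneity = sum(v / (1.0 + abs(i - j)) for (i, j), v in p.items())
    energy = sum(v * v for v in p.values())
    entropy = -sum(v * math.log2(v) for v in p.values() if v > 0)
    if sigma < 1e-12:
        correlation = 0.0
    else:
        correlation = sum((i - mu) * (j - mu) * v for (i, j), v in p.items()) / var

    p_sum = [0.0] * (2 * levels - 1)
    p_diff = [0.0] * levels
    for (i, j), v in p.items():
        p_sum[i + j] += v
        p_diff[abs(i - j)] += v
    sum_average = sum(k * p_sum[k] for k in range(len(p_sum)))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(len(p_sum)))
    sum_of_squares_variance = sum((i - mu) ** 2 * v for (i, j), v in p.items())
    difference_entropy = -sum(v * math.log2(v) for v in p_diff if v > 0)
    mu_d = sum(k * p_diff[k] for k in range(levels))
    difference_variance = sum((k - mu_d) ** 2 * p_diff[k] for k in range(levels))

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


# ----------------------------------------------------------------- LBP oracle

_LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def oracle_lbp_codes(patch, mask):
    """Per-pixel LBP codes for every eligible pixel, nested loops."""
    h, w = patch.shape
    codes = []
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            if not mask[y, x]:
                continue
            if not all(mask[y + dy, x + dx] for dy, dx in _LBP_OFFSETS):
                continue
            code = 0
            for k, (dy, dx) in enumerate(_LBP_OFFSETS):
                if patch[y + dy, x + dx] >= patch[y, x]:
                    code |= 1 << (7 - k)
            codes.append(code)
    return codes


# ----------------------------------------------------------- flood-fill oracle


def oracle_components(mask, connectivity=8):
    """Connected components by BFS flood fill; returns list of
    (area, seed_pixel) sorted by descending area then scan-order seed."""
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            area = 0
            q = deque([(y, x)])
            seen[y, x] = True
            while q:
                cy, cx = q.popleft()
                area += 1
                for dy, dx in nbrs:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        q.append((ny, nx))
            comps.append((area, (y, x)))
    comps.sort(key=lambda c: (-c[0], c[1]))
    return comps


# ------------------------------------------------------------------ AUC oracle


def oracle_auc_all_pairs(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_max_youden(scores, labels, direction):
    """Max J over an exhaustive grid of cutoffs (all score values +/- eps)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    eps = 1e-9 * max(1.0, np.ptp(scores))
    cands = np.concatenate([scores - eps, scores + eps, scores])
    best = -np.inf
    for c in cands:
        called = scores >= c if direction == "HIGH" else scores <= c
        sens = (called & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~called & (labels == 0)).sum() / (labels == 0).sum()
        best = max(best, sens + spec - 1.0)
    return best
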