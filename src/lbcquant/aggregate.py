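"""Case-level aggregation of cluster features.

A case is classified from one row: its cluster count plus seven
distributional summaries (mean, SD, min, max, median, Q75, Q95) of every
cluster-level feature over the case's non-excluded clusters.  Because the
SD of a single observation is undefined, any case with fewer than two
usable clusters is excluded from the cohort with reason ``single_cluster``
rather than imputed.

Quantiles use linear interpolation between order statistics; NaN cluster
values are ignored per feature, and a feature absent in every cluster of a
case yields NaN summaries (its columns are dropped cohort-wide when the
matrix is assembled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExcludedCase", "SUMMARY_NAMES", "aggregate_case", "build_matrix"]

logger = logging.getLogger(__name__)

SUMMARY_NAMES = ("mean", "sd", "min", "max", "median", "q75", "q95")


class EmptyCaseError(ValueError):
    """A case with zero usable clusters (distinct from single-cluster exclusion)."""


@dataclass(frozen=True)
class ExcludedCase:
    case_id: str
    reason: str


def _summaries(values: np.ndarray) -> dict[str, float]:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return {s: float("nan") for s in SUMMARY_NAMES}
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "median": float(np.quantile(v, 0.5)),
        "q75": float(np.quantile(v, 0.75)),
        "q95": float(np.quantile(v, 0.95)),
    }


def aggregate_case(
    clusters: list[dict[str, float]],
    case_id: str,
    label: str,
    menopause: bool,
) -> dict[str, object] | ExcludedCase:
    """Collapse cluster feature dicts into one case row.

    ``clusters`` holds one name → value map per non-excluded cluster.
    Returns an :class:`ExcludedCase` (reason ``single_cluster``) when fewer
    than two clusters are available, mirroring cohort practice; raises
    :class:`EmptyCaseError` for zero clusters, which signals a detection
    failure rather than a legitimate sparse case.
    """
    if len(clusters) == 0:
        raise EmptyCaseError(f"case {case_id}: no clusters detected")
    if len(clusters) == 1:
        return ExcludedCase(case_id, "single_cluster")

    names = sorted({k for c in clusters for k in c})
    row: dict[str, object] = {
        "case_id": case_id,
        "label": label,
        "menopause": bool(menopause),
        "cluster_count": len(clusters),
    }
    for name in names:
        vals = np.array([c.get(name, float("nan")) for c in clusters], dtype=float)
        for stat, value in _summaries(vals).items():
            row[f"{name}__{stat}"] = value
    return row


def build_matrix(
    rows: list[dict[str, object]], include_cluster_count: bool = True
) -> pd.DataFrame:
    """Assemble case rows into the analysis matrix.

    Rows are sorted by ``case_id``; feature columns are ordered by feature
    name then the fixed summary order (mean, sd, min, max, median, q75,
    q95).  Columns with a missing value in any case are dropped with a
    warning, so every retained column is complete.  Requires at least one
    case per class.
    """
    if not rows:
        raise ValueError("no case rows")
    df = pd.DataFrame(rows).set_index("case_id").sort_index()
    labels = df["label"]
    if labels.nunique() < 2:
        raise ValueError("both classes must be present to build a matrix")

    meta = ["label", "menopause"]
    feat_cols = [c for c in df.columns if c not in meta]

    def sort_key(col: str):
        if col == "cluster_count":
            return ("", -1)
        name, _, stat = col.rpartition("__")
        return (name, SUMMARY_NAMES.index(stat))

    feat_cols = sorted(feat_cols, key=sort_key)
    if not include_cluster_count and "cluster_count" in feat_cols:
        feat_cols.remove("cluster_count")

    incomplete = [c for c in feat_cols if df[c].isna().any()]
    if incomplete:
        logger.warning(
            "dropping %d incomplete feature columns (missing in some case): %s",
            len(incomplete),
            incomplete[:10],
        )
        feat_cols = [c for c in feat_cols if c not in incomplete]

    return df[meta + feat_cols]
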