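"""End-to-end composition: images → clusters → features → case matrix → analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import ExcludedCase, aggregate_case, build_matrix
from .detect import DetectionParams, detect_clusters
from .features import GLCMParams, extract_cluster_features
from .select import OOFEvaluation, SearchConfig, oof_evaluate
from .synthetic import SlideCase
from .univariate import rank_features

__all__ = ["cases_to_matrix", "encode_labels", "analyze_matrix", "AnalysisResult"]


def cases_to_matrix(
    cases: list[SlideCase],
    detection: DetectionParams = DetectionParams(),
    glcm: GLCMParams = GLCMParams(),
    target_mpp: float = 2.0,
    exclusion_masks: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, list[ExcludedCase]]:
    """Run detection and feature extraction, then aggregate per case.

    Returns the case-level feature matrix (string labels) and the list of
    excluded cases (fewer than two usable clusters).  Cases where nothing
    at all is detected are excluded with reason ``no_clusters``.
    """
    rows = []
    excluded: list[ExcludedCase] = []
    for case in cases:
        mask = (exclusion_masks or {}).get(case.case_id)
        annotations = detect_clusters(case, detection, exclusion_mask=mask)
        usable = [a for a in annotations if not a.excluded]
        if not usable:
            excluded.append(ExcludedCase(case.case_id, "no_clusters"))
            continue
        vectors = [
            extract_cluster_features(case, a, glcm, target_mpp) for a in usable
        ]
        row = aggregate_case(vectors, case.case_id, case.label, case.menopause)
        if isinstance(row, ExcludedCase):
            excluded.append(row)
        else:
            rows.append(row)
    return build_matrix(rows), excluded


def encode_labels(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map string labels to 0 (normal) / 1 (lesion) for the analysis stages."""
    out = matrix.copy()
    if out["label"].dtype == object:
        out["label"] = (out["label"] == "lesion").astype(int)
    return out


@dataclass
class AnalysisResult:
    univariable: pd.DataFrame
    univariable_menopause: pd.DataFrame | None
    evaluation: OOFEvaluation


def analyze_matrix(
    matrix: pd.DataFrame,
    config: SearchConfig = SearchConfig(),
    top_k: int | None = 10,
    subgroup_tables: bool = True,
) -> AnalysisResult:
    """Univariable ranking plus nested-CV multivariable evaluation.

    The post-menopausal subgroup table is produced when that subgroup
    contains both classes; multivariable modeling runs on the full cohort
    only (subgroups are typically too small to support nested CV).
    """
    m = encode_labels(matrix)
    uni = rank_features(m, top_k=top_k)
    uni_meno = None
    if subgroup_tables:
        sub = m[m["menopause"].astype(bool)]
        if sub["label"].nunique() == 2:
            uni_meno = rank_features(m, top_k=top_k, subgroup="menopause")
    evaluation = oof_evaluate(m, config)
    return AnalysisResult(uni, uni_meno, evaluation)
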