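"""Univariable ROC screening of case-level features.

Each feature is scored by the area under the ROC curve against the lesion
label (the Mann–Whitney probability that a lesion case outranks a normal
case, counting ties half).  AUCs below 0.5 are reported on the oriented
scale 1 − AUC with direction ``LOW`` (lesion takes *lower* values), so
every reported AUC is in [0.5, 1] with an explicit direction — the form in
which ranked screening tables are usually printed.  The operating point is
chosen by the Youden index J = sensitivity + specificity − 1 over an
exhaustive scan of candidate cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ROCResult", "roc_auc", "orient", "youden_point", "rank_features"]


@dataclass(frozen=True)
class ROCResult:
    feature_name: str
    auc: float  # oriented, in [0.5, 1]
    direction: str  # "HIGH" | "LOW": whether lesion takes higher or lower values
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    uninformative: bool = False
    multiple_maxima: bool = False


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("both classes must be present")
    return labels == 1, labels == 0


def roc_auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + ½ P(tie).

    Computed by the rank formula, which is exactly the all-pairs count
    with ties counted half.  NaN scores are excluded pairwise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    pos, neg = _check_classes(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def orient(auc_raw: float) -> tuple[float, str, bool]:
    """Fold a raw AUC to [0.5, 1] with a direction label.

    Returns ``(auc, direction, uninformative)``; direction ``LOW`` means
    the lesion class takes lower feature values.  Exactly 0.5 is reported
    HIGH by convention and flagged uninformative.
    """
    if auc_raw < 0.5:
        return 1.0 - auc_raw, "LOW", False
    return float(auc_raw), "HIGH", auc_raw == 0.5


def youden_point(
    scores, labels, direction: str = "HIGH"
) -> tuple[float, float, float, bool]:
    """Youden-optimal cutoff for the given orientation.

    Candidate cutoffs are midpoints between consecutive distinct sorted
    scores plus one candidate below the minimum and one above the maximum.
    A case is called positive when score >= cutoff (HIGH) or
    score <= cutoff (LOW).  Ties on J are broken by higher specificity,
    then lower cutoff.  Returns ``(cutoff, sensitivity, specificity,
    multiple_maxima)``; the flag marks distinct candidate cutoffs sharing
    the maximal J.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    pos, neg = _check_classes(labels)
    n_pos, n_neg = pos.sum(), neg.sum()

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    candidates = np.concatenate(
        [[distinct[0] - span], mids, [distinct[-1] + span]]
    )

    evaluated = []
    for c in candidates:
        called = scores >= c if direction == "HIGH" else scores <= c
        sens = float((called & pos).sum() / n_pos)
        spec = float((~called & neg).sum() / n_neg)
        evaluated.append((sens + spec - 1.0, spec, -float(c), sens))
    max_j = max(e[0] for e in evaluated)
    at_max = [e for e in evaluated if abs(e[0] - max_j) <= 1e-12]
    j, spec, neg_c, sens = max(at_max)
    return -neg_c, sens, spec, len(at_max) > 1


def rank_features(
    matrix: pd.DataFrame,
    top_k: int | None = 10,
    subgroup: str | None = None,
) -> pd.DataFrame:
    """Ranked per-feature ROC table.

    ``matrix`` is a case × feature frame carrying ``label`` (0/1) and
    ``menopause`` metadata columns (as built by
    :func:`lbcquant.aggregate.build_matrix` or the synthetic generator,
    with labels mapped to 0/1).  ``subgroup="menopause"`` restricts to
    post-menopausal cases.  Features are sorted by oriented AUC descending,
    ties broken by feature name; ``top_k=None`` returns the full table.
    """
    df = matrix
    if subgroup == "menopause":
        df = df[df["menopause"].astype(bool)]
    labels = df["label"].to_numpy().astype(int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        where = f"subgroup {subgroup}" if subgroup else "cohort"
        raise ValueError(f"both classes required in {where}")

    results = []
    for col in df.columns:
        if col in ("label", "menopause"):
            continue
        scores = df[col].to_numpy(dtype=float)
        raw = roc_auc(scores, labels)
        auc, direction, uninformative = orient(raw)
        cutoff, sens, spec, multi = youden_point(scores, labels, direction)
        results.append(
            ROCResult(
                feature_name=col,
                auc=auc,
                direction=direction,
                cutoff=cutoff,
                sensitivity=sens,
                specificity=spec,
                n_pos=int(labels.sum()),
                n_neg=int(labels.size - labels.sum()),
                uninformative=uninformative,
                multiple_maxima=multi,
            )
        )
    table = pd.DataFrame([r.__dict__ for r in results])
    table = table.sort_values(
        ["auc", "feature_name"], ascending=[False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table
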