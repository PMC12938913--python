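"""Multivariable evaluation: beam-search feature selection inside nested CV.

The multivariable procedure is a random-forest classifier over a compact
feature panel found by a beam-search wrapper: starting from all single
features, the best ``beam_width`` subsets at each size are extended by one
unused feature at a time up to ``max_subset_size``, and every candidate
subset is scored by the mean inner-CV AUC of a random forest tuned jointly
over number of trees, mtry, minimal node size and split rule, with class
weights inverse to class frequencies.

Performance is estimated from out-of-fold (OOF) predictions of a
stratified 5-fold cross-validation: selection and tuning run on each outer
training fold only (``panel_mode="per-fold"``), so the held-out cases never
influence the panel — the leakage-free protocol.  ``panel_mode="locked"``
instead selects one panel on the full matrix before splitting; it mirrors a
reported fixed panel but leaks selection information into the CV estimate,
and exists chiefly so the optimism of that shortcut can be measured.

The pooled OOF scores yield the CV AUC, a DeLong 95% confidence interval,
and a Youden operating point.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .univariate import roc_auc, youden_point

__all__ = [
    "SearchConfig",
    "OOFEvaluation",
    "stratified_folds",
    "fit_rf",
    "beam_search_select",
    "oof_evaluate",
    "delong_ci",
]


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the beam search and the random-forest grid.

    ``mtry`` entries may be integers or the tokens ``"1"``, ``"sqrt"``
    (⌈√p⌉) and ``"half"`` (⌈p/2⌉), resolved against the candidate subset
    size p.  ``split_rule`` ``"gini"`` uses standard impurity-minimizing
    splits; ``"random"`` uses extremely-randomized (random-threshold)
    splits.  Outer CV is stratified 5-fold.
    """

    beam_width: int = 5
    max_subset_size: int = 8
    n_trees: tuple[int, ...] = (250, 500, 1000)
    mtry: tuple[object, ...] = ("1", "sqrt", "half")
    min_node_size: tuple[int, ...] = (1, 5, 10)
    split_rule: tuple[str, ...] = ("gini", "random")
    inner_folds: int = 3
    outer_folds: int = 5
    seed: int = 0
    panel_mode: str = "per-fold"  # "per-fold" | "locked"

    def __post_init__(self) -> None:
        if self.beam_width < 1 or self.max_subset_size < 1:
            raise ValueError("beam_width and max_subset_size must be >= 1")
        for name in ("n_trees", "mtry", "min_node_size", "split_rule"):
            if not getattr(self, name):
                raise ValueError(f"empty grid for {name}")
        if self.panel_mode not in ("per-fold", "locked"):
            raise ValueError("panel_mode must be 'per-fold' or 'locked'")

    @staticmethod
    def fast(seed: int = 0, **overrides) -> "SearchConfig":
        """A reduced configuration sized for simulation studies.

        Narrow beam, small panels and a single grid point keep repeated
        nested-CV runs tractable while preserving the wrapper's structure.
        """
        base = dict(
            beam_width=2,
            max_subset_size=2,
            n_trees=(60,),
            mtry=("sqrt",),
            min_node_size=(5,),
            split_rule=("gini",),
            inner_folds=2,
            seed=seed,
        )
        base.update(overrides)
        return SearchConfig(**base)


@dataclass
class FoldModel:
    fold: int
    subset: tuple[str, ...]
    hyperparameters: dict
    inner_score: float


@dataclass
class OOFEvaluation:
    """Out-of-fold evaluation summary of the nested-CV procedure."""

    fold_models: list[FoldModel]
    fold_assignment: np.ndarray  # outer-fold index per case
    oof_scores: np.ndarray  # one lesion probability per case
    cv_auc: float
    delong_ci: tuple[float, float]
    youden_cutoff: float
    sensitivity: float
    specificity: float


def _derive_seed(*parts) -> int:
    return zlib.crc32(repr(parts).encode()) % (2**31)


def stratified_folds(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (0..k-1 per case), deterministic in seed."""
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} cases for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    assignment = np.empty(labels.size, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = f
    return assignment


def _resolve_mtry(token, p: int) -> int:
    if isinstance(token, (int, np.integer)):
        m = int(token)
    elif token == "1":
        m = 1
    elif token == "sqrt":
        m = int(np.ceil(np.sqrt(p)))
    elif token == "half":
        m = int(np.ceil(p / 2))
    else:
        raise ValueError(f"unknown mtry token {token!r}")
    return min(max(m, 1), p)


def _grid(config: SearchConfig, p: int) -> list[dict]:
    points = []
    seen = set()
    for nt in config.n_trees:
        for mt in config.mtry:
            m = _resolve_mtry(mt, p)
            for node in config.min_node_size:
                for rule in config.split_rule:
                    key = (nt, m, node, rule)
                    if key in seen:
                        continue
                    seen.add(key)
                    points.append(
                        {"n_trees": nt, "mtry": m, "min_node_size": node, "split_rule": rule}
                    )
    return points


def fit_rf(X: np.ndarray, y: np.ndarray, hyper: dict, seed: int):
    """Fit a random forest with inverse-class-frequency case weights.

    Predicted lesion probability is the forest-average leaf class share
    (scikit-learn's soft vote).  Deterministic given ``seed``.
    """
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    counts = np.bincount(y, minlength=2)
    weights = {c: y.size / (2.0 * counts[c]) for c in (0, 1)}
    cls = RandomForestClassifier if hyper["split_rule"] == "gini" else ExtraTreesClassifier
    model = cls(
        n_estimators=hyper["n_trees"],
        max_features=hyper["mtry"],
        min_samples_leaf=hyper["min_node_size"],
        criterion="gini",
        bootstrap=True,
        class_weight=weights,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def _inner_splits(y: np.ndarray, config: SearchConfig, fold_idx: int):
    k = min(config.inner_folds, int(np.bincount(y, minlength=2).min()))
    if k < 2:
        raise ValueError("too few cases per class for inner CV")
    skf = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=_derive_seed(config.seed, fold_idx, "inner")
    )
    return list(skf.split(np.zeros(y.size), y))


def _score_subset(
    X: np.ndarray,
    y: np.ndarray,
    cols: tuple[int, ...],
    splits,
    config: SearchConfig,
    fold_idx: int,
    names: tuple[str, ...],
) -> tuple[float, dict]:
    """Best (mean inner-CV AUC, grid point) for one feature subset."""
    best_score, best_grid = -np.inf, None
    sub_names = tuple(names[c] for c in cols)
    for g in _grid(config, len(cols)):
        aucs = []
        for i, (tr, va) in enumerate(splits):
            seed = _derive_seed(config.seed, fold_idx, sub_names, tuple(sorted(g.items())), i)
            model = fit_rf(X[np.ix_(tr, cols)], y[tr], g, seed)
            p = model.predict_proba(X[np.ix_(va, cols)])[:, 1]
            try:
                aucs.append(roc_auc(p, y[va]))
            except ValueError:  # single-class inner fold (tiny data)
                aucs.append(0.5)
        score = float(np.mean(aucs))
        if score > best_score:
            best_score, best_grid = score, g
    return best_score, best_grid


def beam_search_select(
    X: pd.DataFrame, y, config: SearchConfig, fold_idx: int = 0
) -> tuple[tuple[str, ...], dict, float]:
    """Beam-search wrapper feature selection with joint RF tuning.

    Must only ever see training-fold cases; the caller owns that contract.
    Returns ``(feature_names, hyperparameters, inner_score)`` — the subset
    and grid point with the best mean inner-CV AUC over all sizes, ties
    broken by smaller subset then lexicographic feature names.
    """
    names = tuple(X.columns)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y).astype(int)
    splits = _inner_splits(y, config, fold_idx)

    def tie_key(entry):
        score, cols, _ = entry
        return (-score, len(cols), tuple(names[c] for c in cols))

    scored: dict[tuple[int, ...], tuple[float, dict]] = {}

    def score(cols: tuple[int, ...]) -> tuple[float, dict]:
        if cols not in scored:
            scored[cols] = _score_subset(Xv, y, cols, splits, config, fold_idx, names)
        return scored[cols]

    beam = []
    for j in range(len(names)):
        s, g = score((j,))
        beam.append((s, (j,), g))
    beam.sort(key=tie_key)
    best = beam[0]
    beam = beam[: config.beam_width]

    for _size in range(2, config.max_subset_size + 1):
        candidates = {}
        for _, cols, _g in beam:
            for j in range(len(names)):
                if j in cols:
                    continue
                new = tuple(sorted(cols + (j,)))
                candidates[new] = None
        if not candidates:
            break
        extended = []
        for cols in candidates:
            s, g = score(cols)
            extended.append((s, cols, g))
        extended.sort(key=tie_key)
        beam = extended[: config.beam_width]
        if tie_key(beam[0]) < tie_key(best):
            best = beam[0]

    s, cols, g = best
    return tuple(names[c] for c in cols), g, s


def oof_evaluate(matrix: pd.DataFrame, config: SearchConfig) -> OOFEvaluation:
    """Nested-CV out-of-fold evaluation of the full selection + RF pipeline.

    ``matrix`` carries ``label`` (0/1) and ``menopause`` metadata columns
    plus numeric feature columns.  Each case is scored exactly once, by
    the model from whose training fold it was withheld.
    """
    y = matrix["label"].to_numpy().astype(int)
    X = matrix.drop(columns=[c for c in ("label", "menopause") if c in matrix.columns])
    assignment = stratified_folds(y, config.outer_folds, config.seed)

    locked = None
    if config.panel_mode == "locked":
        locked = beam_search_select(X, y, config, fold_idx=-1)

    oof = np.full(y.size, np.nan)
    fold_models: list[FoldModel] = []
    for f in range(config.outer_folds):
        tr = assignment != f
        te = assignment == f
        if locked is not None:
            subset, hyper, inner = locked
        else:
            subset, hyper, inner = beam_search_select(X.loc[tr], y[tr], config, fold_idx=f)
        cols = list(subset)
        seed = _derive_seed(config.seed, f, subset, "final")
        model = fit_rf(X.loc[tr, cols].to_numpy(float), y[tr], hyper, seed)
        oof[te] = model.predict_proba(X.loc[te, cols].to_numpy(float))[:, 1]
        fold_models.append(FoldModel(f, subset, hyper, inner))

    assert not np.isnan(oof).any(), "every case must receive exactly one OOF score"
    auc, lo, hi = delong_ci(oof, y)
    cutoff, sens, spec, _ = youden_point(oof, y, "HIGH")
    return OOFEvaluation(
        fold_models=fold_models,
        fold_assignment=assignment,
        oof_scores=oof,
        cv_auc=auc,
        delong_ci=(lo, hi),
        youden_cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
    )


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong confidence interval.

    Uses the structural-components (placement-value) variance estimator;
    the CI is auc ± z·SE clipped to [0, 1].  Perfect separation gives zero
    variance and a degenerate interval, reported with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    x = scores[labels == 1]
    yv = scores[labels == 0]
    m, n = x.size, yv.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 cases per class")

    tz = rankdata(np.concatenate([x, yv]))
    tx = rankdata(x)
    ty = rankdata(yv)
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v01 = (tz[:m] - tx) / n  # placements of positives among negatives
    v10 = 1.0 - (tz[m:] - ty) / m
    var = v01.var(ddof=1) / m + v10.var(ddof=1) / n
    if var <= 0:
        warnings.warn("zero DeLong variance (perfect separation); degenerate CI")
        return auc, auc, auc
    se = float(np.sqrt(var))
    z = float(norm.ppf(0.5 + level / 2.0))
    return auc, max(0.0, auc - z * se), min(1.0, auc + z * se)
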