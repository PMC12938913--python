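"""Model selection: folds, RF fitting, beam search, OOF evaluation, DeLong."""

import numpy as np
import pandas as pd
import pytest

from lbcquant import (
    CohortSpec,
    SearchConfig,
    beam_search_select,
    delong_ci,
    fit_rf,
    generate_feature_matrix,
    oof_evaluate,
    roc_auc,
    stratified_folds,
)
from lbcquant.select import _inner_splits, _resolve_mtry, _score_subset


def test_stratified_folds_exact_divisibility():
    labels = np.r_[np.ones(25, int), np.zeros(35, int)]
    folds = stratified_folds(labels, k=5, seed=0)
    for f in range(5):
        sel = folds == f
        assert labels[sel].sum() == 5
        assert (labels[sel] == 0).sum() == 7


def test_stratified_folds_remainder_spread():
    labels = np.r_[np.ones(7, int), np.zeros(20, int)]
    folds = stratified_folds(labels, k=5, seed=1)
    per_fold_pos = [labels[folds == f].sum() for f in range(5)]
    assert set(per_fold_pos) <= {1, 2}


def test_stratified_folds_deterministic():
    labels = np.r_[np.ones(12, int), np.zeros(18, int)]
    a = stratified_folds(labels, 5, seed=9)
    b = stratified_folds(labels, 5, seed=9)
    np.testing.assert_array_equal(a, b)


def test_stratified_folds_small_class_raises():
    labels = np.r_[np.ones(3, int), np.zeros(20, int)]
    with pytest.raises(ValueError):
        stratified_folds(labels, 5, 0)


def test_mtry_token_resolution():
    assert _resolve_mtry("1", 10) == 1
    assert _resolve_mtry("sqrt", 10) == 4  # ceil(sqrt(10))
    assert _resolve_mtry("half", 5) == 3
    assert _resolve_mtry(7, 5) == 5  # clipped to subset size


def _hyper(**kw):
    base = {"n_trees": 50, "mtry": 1, "min_node_size": 1, "split_rule": "gini"}
    base.update(kw)
    return base


def test_fit_rf_separable_training_auc(rng):
    X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    model = fit_rf(X, y, _hyper(), seed=0)
    assert roc_auc(model.predict_proba(X)[:, 1], y) == 1.0


def test_fit_rf_deterministic(rng):
    X = rng.normal(size=(30, 3))
    y = np.r_[np.zeros(15, int), np.ones(15, int)]
    p1 = fit_rf(X, y, _hyper(), seed=5).predict_proba(X)[:, 1]
    p2 = fit_rf(X, y, _hyper(), seed=5).predict_proba(X)[:, 1]
    np.testing.assert_array_equal(p1, p2)


def test_fit_rf_tree_count_stability(rng):
    """Doubling the forest at fixed data changes predictions only mildly —
    the ensemble is already near its limiting vote."""
    X = rng.normal(size=(40, 3))
    X[:20] += 1.0
    y = np.r_[np.ones(20, int), np.zeros(20, int)]
    p1 = fit_rf(X, y, _hyper(n_trees=200), seed=1).predict_proba(X)[:, 1]
    p2 = fit_rf(X, y, _hyper(n_trees=400), seed=1).predict_proba(X)[:, 1]
    assert np.abs(p1 - p2).mean() < 0.1


def test_fit_rf_single_class_raises(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError):
        fit_rf(X, np.ones(10, int), _hyper(), seed=0)


def test_empty_grid_rejected():
    with pytest.raises(ValueError, match="n_trees"):
        SearchConfig(n_trees=())


def _small_matrix(seed=4, effect=1.5, n=25, features=10, informative=2):
    spec = CohortSpec(n_normal=n, n_lesion=n, effect_size=effect, seed=seed)
    return generate_feature_matrix(spec, features, informative)


def _greedy_oracle(X, y, config, fold_idx=0):
    """Independent greedy forward selection (beam width 1 equivalent)."""
    names = tuple(X.columns)
    Xv = X.to_numpy(float)
    y = np.asarray(y).astype(int)
    splits = _inner_splits(y, config, fold_idx)

    def key(entry):
        score, cols = entry[0], entry[1]
        return (-score, len(cols), tuple(names[c] for c in cols))

    current: tuple[int, ...] = ()
    best = None
    for _size in range(1, config.max_subset_size + 1):
        step = []
        for j in range(len(names)):
            if j in current:
                continue
            cols = tuple(sorted(current + (j,)))
            s, g = _score_subset(Xv, y, cols, splits, config, fold_idx, names)
            step.append((s, cols, g))
        if not step:
            break
        step.sort(key=key)
        current = step[0][1]
        if best is None or key(step[0]) < key(best):
            best = step[0]
    return tuple(names[c] for c in best[1]), best[2]


def test_beam_width_one_equals_greedy():
    m = _small_matrix()
    X = m.drop(columns=["label", "menopause"])
    y = m["label"]
    config = SearchConfig.fast(seed=3, beam_width=1, max_subset_size=3, n_trees=(20,))
    subset, hyper, _ = beam_search_select(X, y, config)
    oracle_subset, oracle_hyper = _greedy_oracle(X, y, config)
    assert subset == oracle_subset
    assert hyper == oracle_hyper


def test_max_subset_size_one_picks_best_single_feature():
    m = _small_matrix(effect=2.5)
    X = m.drop(columns=["label", "menopause"])
    config = SearchConfig.fast(seed=0, max_subset_size=1, n_trees=(20,))
    subset, _, _ = beam_search_select(X, m["label"], config)
    assert len(subset) == 1
    assert subset[0] in ("f000", "f001")  # an informative column wins


def test_oof_every_case_scored_once_and_folds_disjoint():
    m = _small_matrix()
    ev = oof_evaluate(m, SearchConfig.fast(seed=2, n_trees=(20,)))
    assert ev.oof_scores.shape == (len(m),)
    assert not np.isnan(ev.oof_scores).any()
    assert set(ev.fold_assignment) == set(range(5))
    lo, hi = ev.delong_ci
    assert lo <= ev.cv_auc <= hi


def test_oof_deterministic():
    m = _small_matrix()
    cfg = SearchConfig.fast(seed=7, n_trees=(20,))
    a = oof_evaluate(m, cfg)
    b = oof_evaluate(m, cfg)
    np.testing.assert_array_equal(a.oof_scores, b.oof_scores)
    assert a.cv_auc == b.cv_auc
    assert [f.subset for f in a.fold_models] == [f.subset for f in b.fold_models]


def test_delong_auc_equals_mannwhitney(rng):
    for _ in range(20):
        scores = rng.integers(0, 10, size=30).astype(float)
        labels = np.r_[np.zeros(2, int), np.ones(2, int), rng.integers(0, 2, 26)]
        auc, _, _ = delong_ci(scores, labels)
        assert auc == pytest.approx(roc_auc(scores, labels), abs=1e-12)


def test_delong_perfect_separation_degenerate():
    scores = np.r_[np.zeros(5), np.ones(5)]
    labels = np.r_[np.zeros(5, int), np.ones(5, int)]
    with pytest.warns(UserWarning, match="zero DeLong variance"):
        auc, lo, hi = delong_ci(scores, labels)
    assert (auc, lo, hi) == (1.0, 1.0, 1.0)


def test_delong_null_ci_covers_half(rng):
    scores = rng.normal(size=1000)
    labels = np.r_[np.zeros(500, int), np.ones(500, int)]
    _, lo, hi = delong_ci(scores, labels)
    assert lo < 0.5 < hi


def test_delong_small_class_raises():
    with pytest.raises(ValueError):
        delong_ci([1.0, 2.0, 3.0], [1, 0, 0])
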