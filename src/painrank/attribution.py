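"""Per-feature attribution for tree ensembles via path decomposition.

Feature importance for the backward-elimination step and for model
interpretation is computed by tree-path attribution (Saabas
decomposition): walking a sample's decision path, each split assigns to
its feature the change in the node's expected output between parent and
child, so the attributions of one tree sum — together with the root
expectation — exactly to the tree's output for that sample. Ensemble
attributions are the ensemble's own combination of its trees:

* random forest — average of per-tree attributions in probability space;
* gradient boosting — sum of per-tree attributions (times the learning
  rate) in margin space, plus the initial raw score;
* AdaBoost — estimator-weight-averaged per-stump attributions in
  probability space (an additive surrogate of the soft vote);
* XGBoost — the booster's native path attributions (``approx_contribs``),
  same semantics, in margin space.

Attributions are used for *ranking* features by mean absolute credit,
so the mix of probability- and margin-space scales across learner
families is deliberate and harmless; the weighted combination across
learners normalizes each matrix's weight, not its scale.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.tree import BaseDecisionTree

__all__ = ["tree_path_attribution", "combine_attributions", "rank_features"]


def _node_values_class1(tree) -> np.ndarray:
    """Per-node class-1 fraction for a fitted classification tree."""
    v = tree.tree_.value[:, 0, :]
    totals = v.sum(axis=1, keepdims=True)
    return (v / np.where(totals > 0, totals, 1.0))[:, -1]


def _node_values_regression(tree) -> np.ndarray:
    return tree.tree_.value[:, 0, 0]


def _single_tree_contrib(tree, X, values: np.ndarray):
    """Vectorized path decomposition for one fitted tree.

    Returns ``(contrib, base)`` with ``contrib`` of shape (n, d);
    ``base + contrib.sum(1)`` equals the tree's per-sample output.
    """
    t = tree.tree_
    n_nodes = t.node_count
    parent = np.full(n_nodes, -1)
    for node in range(n_nodes):
        for child in (t.children_left[node], t.children_right[node]):
            if child != -1:
                parent[child] = node
    delta = np.zeros(n_nodes)
    parent_feature = np.zeros(n_nodes, dtype=np.int64)
    nonroot = parent >= 0
    delta[nonroot] = values[nonroot] - values[parent[nonroot]]
    parent_feature[nonroot] = t.feature[parent[nonroot]]

    d = t.n_features
    rows = np.where(nonroot)[0]
    assign = sparse.csr_matrix(
        (delta[rows], (rows, parent_feature[rows])), shape=(n_nodes, d)
    )
    paths = tree.decision_path(X)  # (n, n_nodes) indicator
    contrib = np.asarray((paths @ assign).todense())
    return contrib, float(values[0])


def tree_path_attribution(model, X):
    """Attribution matrix for a fitted tree model or ensemble.

    Parameters
    ----------
    model : fitted tree learner
        Decision tree, random forest, AdaBoost, gradient boosting, or
        an ``xgboost.XGBClassifier``.
    X : array-like of shape (n_samples, n_features)

    Returns
    -------
    contrib : ndarray (n_samples, n_features)
    base : float
        Expected output; ``base + contrib.sum(axis=1)`` reproduces the
        model's additive output (class-1 probability for trees/forests,
        margin for boosted models, the weighted stump-probability vote
        for AdaBoost).
    """
    X = np.asarray(X, dtype=np.float64)

    if isinstance(model, BaseDecisionTree):
        values = (
            _node_values_class1(model)
            if model.tree_.value.shape[2] > 1
            else _node_values_regression(model)
        )
        return _single_tree_contrib(model, X, values)

    if isinstance(model, RandomForestClassifier):
        total = np.zeros((X.shape[0], model.n_features_in_))
        base = 0.0
        for est in model.estimators_:
            c, b = _single_tree_contrib(est, X, _node_values_class1(est))
            total += c
            base += b
        k = len(model.estimators_)
        return total / k, base / k

    if isinstance(model, GradientBoostingClassifier):
        total = np.zeros((X.shape[0], model.n_features_in_))
        for stage in model.estimators_[:, 0]:
            c, _ = _single_tree_contrib(stage, X, _node_values_regression(stage))
            total += c
        total *= model.learning_rate
        # constant initial raw score (log-odds of the training prior)
        base = float(model._raw_predict_init(X[:1])[0, 0]) + model.learning_rate * sum(
            _node_values_regression(s)[0] for s in model.estimators_[:, 0]
        )
        return total, base

    if isinstance(model, AdaBoostClassifier):
        w = model.estimator_weights_[: len(model.estimators_)]
        w = w / w.sum()
        total = np.zeros((X.shape[0], model.n_features_in_))
        base = 0.0
        for est, wt in zip(model.estimators_, w):
            c, b = _single_tree_contrib(est, X, _node_values_class1(est))
            total += wt * c
            base += wt * b
        return total, base

    # xgboost exposes the same path attribution natively
    try:
        import xgboost as xgb
    except ImportError:  # pragma: no cover
        xgb = None
    if xgb is not None and isinstance(model, xgb.XGBClassifier):
        booster = model.get_booster()
        contribs = booster.predict(
            xgb.DMatrix(X), pred_contribs=True, approx_contribs=True
        )
        return contribs[:, :-1], float(contribs[0, -1])

    raise TypeError(f"unsupported model type for path attribution: {type(model).__name__}")


def combine_attributions(matrices, weights) -> np.ndarray:
    """Weight-normalized sum of per-learner attribution matrices."""
    weights = np.asarray(weights, dtype=float)
    if len(matrices) != weights.size:
        raise ValueError("one weight per attribution matrix required")
    if weights.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    shapes = {m.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"attribution matrices disagree in shape: {shapes}")
    w = weights / weights.sum()
    return sum(wi * np.asarray(m) for wi, m in zip(w, matrices))


def rank_features(contrib: np.ndarray, feature_names) -> list[str]:
    """Feature names ordered by decreasing mean |attribution|."""
    imp = np.abs(np.asarray(contrib)).mean(axis=0)
    order = np.argsort(-imp, kind="stable")
    return [feature_names[i] for i in order]
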