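"""Exact per-prediction Shapley values for decision-tree ensembles.

Implements the polynomial-time path-dependent tree-Shapley algorithm: for
one prediction, the algorithm walks every root-to-leaf path while
maintaining, for each *unique* feature split on along the path, the
fraction of conditioned subsets that flow down ("one fraction") and the
cover-weighted fraction of unconditioned subsets ("zero fraction"),
together with permutation weights for every possible subset size (the
EXTEND/UNWIND recurrences).  Feature absence is modelled by the tree's own
training cover: at an unconditioned split, weight is distributed to the
children proportionally to their training sample weight.

The result satisfies local accuracy exactly:

    f(x) = base_value + sum_j phi_j(x)

where ``base_value`` is the cover-weighted mean leaf value.  Complexity is
O(trees * leaves * depth^2) per explained row; hot loops compile with numba
when available and run as plain Python otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "forest_shap_values"]


def _extend_path(feature_indexes, zero_fractions, one_fractions, pweights,
                 unique_depth, zero_fraction, one_fraction, feature_index):
    feature_indexes[unique_depth] = feature_index
    zero_fractions[unique_depth] = zero_fraction
    one_fractions[unique_depth] = one_fraction
    if unique_depth == 0:
        pweights[unique_depth] = 1.0
    else:
        pweights[unique_depth] = 0.0
    for i in range(unique_depth - 1, -1, -1):
        pweights[i + 1] += one_fraction * pweights[i] * (i + 1.0) / (unique_depth + 1.0)
        pweights[i] = zero_fraction * pweights[i] * (unique_depth - i) / (unique_depth + 1.0)


def _unwind_path(feature_indexes, zero_fractions, one_fractions, pweights,
                 unique_depth, path_index):
    one_fraction = one_fractions[path_index]
    zero_fraction = zero_fractions[path_index]
    next_one_portion = pweights[unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pweights[i]
            pweights[i] = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            next_one_portion = tmp - pweights[i] * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        else:
            pweights[i] = (pweights[i] * (unique_depth + 1.0)) / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        feature_indexes[i] = feature_indexes[i + 1]
        zero_fractions[i] = zero_fractions[i + 1]
        one_fractions[i] = one_fractions[i + 1]


def _unwound_path_sum(feature_indexes, zero_fractions, one_fractions, pweights,
                      unique_depth, path_index):
    one_fraction = one_fractions[path_index]
    zero_fraction = zero_fractions[path_index]
    next_one_portion = pweights[unique_depth]
    total = 0.0
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one_portion = pweights[i] - tmp * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        else:
            total += (pweights[i] / zero_fraction) / ((unique_depth - i) / (unique_depth + 1.0))
    return total


def _tree_shap_recursive(children_left, children_right, features, thresholds,
                         values, node_sample_weight, x, phi, node_index,
                         unique_depth, parent_feature_indexes,
                         parent_zero_fractions, parent_one_fractions,
                         parent_pweights, parent_zero_fraction,
                         parent_one_fraction, parent_feature_index):
    # each recursion level works on a fresh slice of the shared path arrays
    feature_indexes = parent_feature_indexes[unique_depth + 1:]
    zero_fractions = parent_zero_fractions[unique_depth + 1:]
    one_fractions = parent_one_fractions[unique_depth + 1:]
    pweights = parent_pweights[unique_depth + 1:]
    feature_indexes[: unique_depth + 1] = parent_feature_indexes[: unique_depth + 1]
    zero_fractions[: unique_depth + 1] = parent_zero_fractions[: unique_depth + 1]
    one_fractions[: unique_depth + 1] = parent_one_fractions[: unique_depth + 1]
    pweights[: unique_depth + 1] = parent_pweights[: unique_depth + 1]

    _extend_path(feature_indexes, zero_fractions, one_fractions, pweights,
                 unique_depth, parent_zero_fraction, parent_one_fraction,
                 parent_feature_index)

    if children_left[node_index] < 0:  # leaf
        for i in range(1, unique_depth + 1):
            w = _unwound_path_sum(feature_indexes, zero_fractions,
                                  one_fractions, pweights, unique_depth, i)
            phi[feature_indexes[i]] += (
                w * (one_fractions[i] - zero_fractions[i]) * values[node_index]
            )
        return

    split_index = features[node_index]
    cleft = children_left[node_index]
    cright = children_right[node_index]
    if x[split_index] <= thresholds[node_index]:
        hot_index, cold_index = cleft, cright
    else:
        hot_index, cold_index = cright, cleft
    w = node_sample_weight[node_index]
    hot_zero_fraction = node_sample_weight[hot_index] / w
    cold_zero_fraction = node_sample_weight[cold_index] / w
    incoming_zero_fraction = 1.0
    incoming_one_fraction = 1.0

    # if this feature was already split on upstream, undo that split so the
    # path keeps one entry per unique feature
    path_index = 0
    while path_index <= unique_depth:
        if feature_indexes[path_index] == split_index:
            break
        path_index += 1
    if path_index != unique_depth + 1:
        incoming_zero_fraction = zero_fractions[path_index]
        incoming_one_fraction = one_fractions[path_index]
        _unwind_path(feature_indexes, zero_fractions, one_fractions, pweights,
                     unique_depth, path_index)
        unique_depth -= 1

    _tree_shap_recursive(children_left, children_right, features, thresholds,
                         values, node_sample_weight, x, phi, hot_index,
                         unique_depth + 1, feature_indexes, zero_fractions,
                         one_fractions, pweights,
                         hot_zero_fraction * incoming_zero_fraction,
                         incoming_one_fraction, split_index)
    _tree_shap_recursive(children_left, children_right, features, thresholds,
                         values, node_sample_weight, x, phi, cold_index,
                         unique_depth + 1, feature_indexes, zero_fractions,
                         one_fractions, pweights,
                         cold_zero_fraction * incoming_zero_fraction,
                         0.0, split_index)


def _tree_shap_single(children_left, children_right, features, thresholds,
                      values, node_sample_weight, max_depth, x, phi):
    s = (max_depth + 2) * (max_depth + 3) // 2
    feature_indexes = np.zeros(s, dtype=np.int64)
    zero_fractions = np.zeros(s, dtype=np.float64)
    one_fractions = np.zeros(s, dtype=np.float64)
    pweights = np.zeros(s, dtype=np.float64)
    _tree_shap_recursive(children_left, children_right, features, thresholds,
                         values, node_sample_weight, x, phi, 0, 0,
                         feature_indexes, zero_fractions, one_fractions,
                         pweights, 1.0, 1.0, -1)


def _tree_shap_batch(children_left, children_right, features, thresholds,
                     values, node_sample_weight, max_depth, X, phi):
    for r in range(X.shape[0]):
        _tree_shap_single(children_left, children_right, features, thresholds,
                          values, node_sample_weight, max_depth, X[r], phi[r])


try:  # compile the hot loops when numba is available
    from numba import njit as _njit

    # no on-disk caching: numba's cache is unreliable for self-recursive
    # functions (can segfault on reload), so compile once per process
    _extend_path = _njit(cache=False)(_extend_path)
    _unwind_path = _njit(cache=False)(_unwind_path)
    _unwound_path_sum = _njit(cache=False)(_unwound_path_sum)
    _tree_shap_recursive = _njit(cache=False)(_tree_shap_recursive)
    _tree_shap_single = _njit(cache=False)(_tree_shap_single)
    _tree_shap_batch = _njit(cache=False)(_tree_shap_batch)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False


def _leaf_values(tree) -> np.ndarray:
    """Per-node output value; class-1 probability for binary classifiers."""
    v = tree.tree_.value
    if v.shape[1] == 1 and v.shape[2] == 2:  # binary classification
        v = v[:, 0, :]
        totals = v.sum(axis=1)
        out = np.where(totals > 0, v[:, 1] / np.maximum(totals, 1e-300), 0.0)
        # sklearn >= 1.4 already stores per-class fractions; renormalizing
        # is then a no-op
        return out.astype(np.float64)
    return v[:, 0, 0].astype(np.float64)


def tree_shap_values(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values and base value for a single fitted sklearn tree.

    Parameters
    ----------
    tree : fitted DecisionTreeClassifier / DecisionTreeRegressor
    X : float array (n_rows, n_features)

    Returns
    -------
    (phi, base) where ``phi`` has shape (n_rows, n_features) and
    ``base + phi.sum(1)`` equals the tree's prediction for each row.
    """
    t = tree.tree_
    X = np.ascontiguousarray(X, dtype=np.float64)
    values = _leaf_values(tree)
    weights = t.weighted_n_node_samples.astype(np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    _tree_shap_batch(
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        values, weights, int(t.max_depth), X, phi,
    )
    leaves = t.children_left < 0
    base = float(np.sum(weights[leaves] * values[leaves]) / weights[0])
    return phi, base


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values for a sklearn forest (mean over member trees).

    For a :class:`RandomForestClassifier` the explained output is the
    predicted probability of the positive class.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    base = 0.0
    for est in forest.estimators_:
        p, b = tree_shap_values(est, X)
        phi += p
        base += b
    k = len(forest.estimators_)
    return phi / k, base / k
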