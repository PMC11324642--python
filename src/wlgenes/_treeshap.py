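"""Exact path-dependent Shapley attribution for sklearn tree ensembles.

Implements the polynomial-time TreeSHAP recursion: for each sample and tree,
weights of all feature subsets consistent with the tree's cover fractions are
maintained along the root-to-leaf paths, giving each feature's exact Shapley
value with respect to the tree's own conditional expectation.  Attributions
are additive by construction: base_value + sum(phi) equals the model output
(probability of the stress class) for every sample.
"""

from __future__ import annotations

import numpy as np

# a path element is [feature_index, zero_fraction, one_fraction, pweight]
_F, _Z, _O, _W = 0, 1, 2, 3


def _extend(path: list[list[float]], depth: int, zero: float, one: float, feat: int) -> None:
    path.append([feat, zero, one, 1.0 if depth == 0 else 0.0])
    for i in range(depth - 1, -1, -1):
        path[i + 1][_W] += one * path[i][_W] * (i + 1) / (depth + 1)
        path[i][_W] = zero * path[i][_W] * (depth - i) / (depth + 1)


def _unwind(path: list[list[float]], depth: int, idx: int) -> None:
    one = path[idx][_O]
    zero = path[idx][_Z]
    nxt = path[depth][_W]
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = path[i][_W]
            path[i][_W] = nxt * (depth + 1) / ((i + 1) * one)
            nxt = tmp - path[i][_W] * zero * (depth - i) / (depth + 1)
        else:
            path[i][_W] = path[i][_W] * (depth + 1) / (zero * (depth - i))
    for i in range(idx, depth):
        path[i][_F] = path[i + 1][_F]
        path[i][_Z] = path[i + 1][_Z]
        path[i][_O] = path[i + 1][_O]
    path.pop()


def _unwound_sum(path: list[list[float]], depth: int, idx: int) -> float:
    one = path[idx][_O]
    zero = path[idx][_Z]
    nxt = path[depth][_W]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (depth + 1) / ((i + 1) * one)
            total += tmp
            nxt = path[i][_W] - tmp * zero * (depth - i) / (depth + 1)
        else:
            total += path[i][_W] / (zero * (depth - i) / (depth + 1))
    return total


def _recurse(
    tree,
    leaf_values: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray,
    node: int,
    depth: int,
    parent_path: list[list[float]],
    parent_zero: float,
    parent_one: float,
    parent_feat: int,
) -> None:
    path = [el[:] for el in parent_path]
    _extend(path, depth, parent_zero, parent_one, parent_feat)
    left = tree.children_left[node]
    right = tree.children_right[node]
    if left < 0:  # leaf
        for i in range(1, depth + 1):
            w = _unwound_sum(path, depth, i)
            phi[int(path[i][_F])] += w * (path[i][_O] - path[i][_Z]) * leaf_values[node]
        return
    feat = int(tree.feature[node])
    if x[feat] <= tree.threshold[node]:
        hot, cold = left, right
    else:
        hot, cold = right, left
    cover = tree.weighted_n_node_samples
    hot_zero = cover[hot] / cover[node]
    cold_zero = cover[cold] / cover[node]
    inc_zero = 1.0
    inc_one = 1.0
    # feature already on the path: undo its previous split before re-splitting
    for k in range(1, depth + 1):
        if int(path[k][_F]) == feat:
            inc_zero = path[k][_Z]
            inc_one = path[k][_O]
            _unwind(path, depth, k)
            depth -= 1
            break
    _recurse(tree, leaf_values, x, phi, hot, depth + 1, path, hot_zero * inc_zero, inc_one, feat)
    _recurse(tree, leaf_values, x, phi, cold, depth + 1, path, cold_zero * inc_zero, 0.0, feat)


def _leaf_prob(tree) -> np.ndarray:
    """Per-node probability of class 1 from the tree's value array."""
    v = tree.value.reshape(tree.node_count, -1)
    totals = v.sum(axis=1)
    totals[totals == 0] = 1.0
    return v[:, -1] / totals


def tree_expected_value(tree) -> float:
    """Cover-weighted mean leaf probability (the tree's base value)."""
    probs = _leaf_prob(tree)
    leaves = tree.children_left < 0
    w = tree.weighted_n_node_samples[leaves]
    return float((probs[leaves] * w).sum() / w.sum())


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions for a fitted sklearn forest classifier.

    Parameters
    ----------
    forest : fitted ensemble with ``estimators_`` of decision trees
    X : array (n_samples, n_features)

    Returns
    -------
    phi : array (n_samples, n_features) — per-sample attributions towards the
        probability of class 1
    base_value : float — mean over trees of the cover-weighted leaf probability
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    phi = np.zeros((n, p))
    base = 0.0
    T = len(forest.estimators_)
    for est in forest.estimators_:
        tree = est.tree_
        leaf_values = _leaf_prob(tree)
        base += tree_expected_value(tree) / T
        for j in range(n):
            tphi = np.zeros(p)
            _recurse(tree, leaf_values, X[j], tphi, 0, 0, [], 1.0, 1.0, -1)
            phi[j] += tphi / T
    return phi, base
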