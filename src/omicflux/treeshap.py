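"""Exact additive feature attribution for decision-tree ensembles.

Path-dependent tree attribution: the conditional expectation of a tree's
output given a feature subset follows the tree's own cover (training sample
counts) at splits on hidden features.  Attributions are exact Shapley
values of that set function, computed in polynomial time by tracking, along
each root-to-leaf path, the proportion of feature subsets that let the path
be followed.

Local accuracy holds exactly: per sample, base value + sum of attributions
equals the tree's output.  Ensemble attributions are the mean over trees,
matching a random forest's averaged probabilities.

``brute_force_shap_tree`` recomputes the same quantity by explicit
enumeration over feature subsets and serves as an independent oracle in
tests; it is exponential in the number of distinct features a tree uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Sequence

import numpy as np

__all__ = [
    "tree_shap_values",
    "forest_shap_values",
    "expected_value_tree",
    "brute_force_shap_tree",
]


@dataclass
class _TreeArrays:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    values: np.ndarray  # (n_nodes, n_outputs), leaf rows hold the output
    cover: np.ndarray  # weighted_n_node_samples


def _extract(tree) -> _TreeArrays:
    """Pull arrays out of a fitted sklearn tree (classifier or regressor)."""
    t = tree.tree_
    raw = t.value  # (n_nodes, 1, n_out) — class counts/proportions or means
    vals = raw[:, 0, :].astype(float)
    if vals.shape[1] > 1:
        # classifier: normalize node class tallies to probabilities
        sums = vals.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        vals = vals / sums
    return _TreeArrays(
        children_left=t.children_left,
        children_right=t.children_right,
        feature=t.feature,
        threshold=t.threshold,
        values=vals,
        cover=t.weighted_n_node_samples.astype(float),
    )


def expected_value_tree(tree) -> np.ndarray:
    """Cover-weighted mean leaf output — the attribution base value."""
    arr = _extract(tree)
    leaves = arr.children_left == -1
    w = arr.cover[leaves] / arr.cover[0]
    return w @ arr.values[leaves]


# ---------------------------------------------------------------------------
# Polynomial-time path algorithm
# ---------------------------------------------------------------------------
# The unique path is a list of elements (feature, zero_fraction, one_fraction,
# pweight): zero_fraction is the cover proportion flowing this way when the
# feature is hidden, one_fraction is 1 if x follows this branch else 0, and
# pweight accumulates the permutation weights of subsets of that path.


def _extend(path: list[list], zero_frac: float, one_frac: float, feat: int) -> None:
    depth = len(path)
    path.append([feat, zero_frac, one_frac, 1.0 if depth == 0 else 0.0])
    for i in range(depth - 1, -1, -1):
        path[i + 1][3] += one_frac * path[i][3] * (i + 1) / (depth + 1)
        path[i][3] = zero_frac * path[i][3] * (depth - i) / (depth + 1)


def _unwind(path: list[list], index: int) -> None:
    depth = len(path) - 1
    one_frac = path[index][2]
    zero_frac = path[index][1]
    next_one = path[depth][3]
    for i in range(depth - 1, -1, -1):
        if one_frac != 0:
            tmp = path[i][3]
            path[i][3] = next_one * (depth + 1) / ((i + 1) * one_frac)
            next_one = tmp - path[i][3] * zero_frac * (depth - i) / (depth + 1)
        else:
            path[i][3] = path[i][3] * (depth + 1) / (zero_frac * (depth - i))
    for i in range(index, depth):
        path[i][0] = path[i + 1][0]
        path[i][1] = path[i + 1][1]
        path[i][2] = path[i + 1][2]
    path.pop()


def _unwound_sum(path: list[list], index: int) -> float:
    depth = len(path) - 1
    one_frac = path[index][2]
    zero_frac = path[index][1]
    next_one = path[depth][3]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one_frac != 0:
            tmp = next_one * (depth + 1) / ((i + 1) * one_frac)
            total += tmp
            next_one = path[i][3] - tmp * zero_frac * (depth - i) / (depth + 1)
        else:
            total += path[i][3] * (depth + 1) / (zero_frac * (depth - i))
    return total


def _tree_shap_single(arr: _TreeArrays, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(
        node: int,
        path: list[list],
        zero_frac: float,
        one_frac: float,
        feat: int,
    ) -> None:
        path = [el.copy() for el in path]
        _extend(path, zero_frac, one_frac, feat)
        if arr.children_left[node] == -1:
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[path[i][0]] += (
                    w * (path[i][2] - path[i][1]) * arr.values[node]
                )
            return
        split = int(arr.feature[node])
        left, right = int(arr.children_left[node]), int(arr.children_right[node])
        if x[split] <= arr.threshold[node]:
            hot, cold = left, right
        else:
            hot, cold = right, left
        hot_frac = arr.cover[hot] / arr.cover[node]
        cold_frac = arr.cover[cold] / arr.cover[node]
        incoming_zero, incoming_one = 1.0, 1.0
        found = -1
        for i in range(1, len(path)):
            if path[i][0] == split:
                found = i
                break
        if found >= 0:
            incoming_zero = path[found][1]
            incoming_one = path[found][2]
            _unwind(path, found)
        recurse(hot, path, incoming_zero * hot_frac, incoming_one, split)
        recurse(cold, path, incoming_zero * cold_frac, 0.0, split)

    recurse(0, [], 1.0, 1.0, -1)


def tree_shap_values(tree, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attributions for one fitted sklearn tree.

    Returns ``(phi, base)`` with ``phi`` of shape
    (n_samples, n_features, n_outputs) and ``base`` of shape (n_outputs,);
    for every sample, ``base + phi.sum(features)`` equals the tree output.
    """
    arr = _extract(tree)
    # sklearn predicts on float32 inputs; mirror the cast so threshold
    # comparisons route samples to the same leaves
    X = np.asarray(X, dtype=np.float32).astype(float)
    if X.ndim == 1:
        X = X[None, :]
    n_samples, n_features = X.shape
    n_out = arr.values.shape[1]
    phi = np.zeros((n_samples, n_features, n_out))
    for s in range(n_samples):
        _tree_shap_single(arr, X[s], phi[s])
    base = expected_value_tree(tree)
    return phi, base


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-tree attributions for a sklearn forest ensemble.

    The forest's probability output is the mean of its trees' outputs, so
    the mean of per-tree attributions and base values preserves local
    accuracy for the ensemble.
    """
    estimators = forest.estimators_
    phi_total = None
    base_total = None
    for tree in estimators:
        phi, base = tree_shap_values(tree, X)
        phi_total = phi if phi_total is None else phi_total + phi
        base_total = base if base_total is None else base_total + base
    return phi_total / len(estimators), base_total / len(estimators)


# ---------------------------------------------------------------------------
# Independent brute-force oracle (exponential; tests only)
# ---------------------------------------------------------------------------


def _conditional_expectation(
    arr: _TreeArrays, x: np.ndarray, known: frozenset
) -> np.ndarray:
    def walk(node: int) -> np.ndarray:
        if arr.children_left[node] == -1:
            return arr.values[node]
        split = int(arr.feature[node])
        left, right = int(arr.children_left[node]), int(arr.children_right[node])
        if split in known:
            nxt = left if x[split] <= arr.threshold[node] else right
            return walk(nxt)
        wl = arr.cover[left] / arr.cover[node]
        wr = arr.cover[right] / arr.cover[node]
        return wl * walk(left) + wr * walk(right)

    return walk(0)


def brute_force_shap_tree(tree, x: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Shapley values of the path-dependent expectation, by enumeration."""
    arr = _extract(tree)
    x = np.asarray(x, dtype=np.float32).astype(float)  # match sklearn routing
    used = sorted({int(f) for f in arr.feature if f >= 0})
    n_features = x.shape[0]
    n_out = arr.values.shape[1]
    phi = np.zeros((n_features, n_out))
    d = len(used)
    for i in used:
        others = [f for f in used if f != i]
        for mask in range(1 << len(others)):
            subset = frozenset(
                others[k] for k in range(len(others)) if mask >> k & 1
            )
            s = len(subset)
            weight = factorial(s) * factorial(d - s - 1) / factorial(d)
            gain = _conditional_expectation(
                arr, x, subset | {i}
            ) - _conditional_expectation(arr, x, subset)
            phi[i] += weight * gain
    base = _conditional_expectation(arr, x, frozenset())
    return phi, base
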