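"""Exact path-dependent TreeSHAP for scikit-learn tree ensembles.

Computes Shapley-value feature attributions for regression trees under the
tree-path-dependent value function: for a feature subset S, the model value
f_S(x) follows x's split at nodes whose feature is in S and averages both
children (weighted by training cover) elsewhere. Attributions are exact —
for each leaf, the polynomial-weight recursion of the standard tree-SHAP
algorithm is evaluated over the leaf's (duplicate-merged) path, which is
algebraically identical to the recursive EXTEND/UNWIND formulation but
iterates leaves independently, making it straightforward to JIT-compile.

Local accuracy holds by construction: base value + sum of attributions equals
the tree's prediction, and attributions average over trees for a forest.

The brute-force subset-enumeration oracle (:func:`brute_force_shap`) exists
for verification on small trees only; it is exponential in the number of
distinct features the tree uses.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
from numba import njit

__all__ = ["shap_values", "tree_shap_single", "brute_force_shap"]


@njit(cache=True)
def _leaf_shap(
    x,
    children_left,
    children_right,
    feature,
    threshold,
    values,
    cover,
    phi,
):
    """Accumulate attributions for one sample over one tree (all leaves)."""
    n_nodes = children_left.shape[0]
    # longest root->leaf node chain
    depth = np.zeros(n_nodes, dtype=np.int64)
    max_depth = 0
    for node in range(n_nodes):
        if children_left[node] >= 0:
            for child in (children_left[node], children_right[node]):
                depth[child] = depth[node] + 1
                if depth[child] > max_depth:
                    max_depth = depth[child]
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for node in range(n_nodes):
        if children_left[node] >= 0:
            parent[children_left[node]] = node
            parent[children_right[node]] = node

    chain = np.empty(max_depth + 1, dtype=np.int64)
    uf = np.empty(max_depth + 1, dtype=np.int64)  # unique features on path
    uz = np.empty(max_depth + 1, dtype=np.float64)  # merged zero fractions
    uo = np.empty(max_depth + 1, dtype=np.float64)  # merged one fractions
    w = np.empty(max_depth + 2, dtype=np.float64)  # path weights incl. dummy

    for leaf in range(n_nodes):
        if children_left[leaf] >= 0:
            continue
        # path from root to this leaf
        k = 0
        node = leaf
        while node >= 0:
            chain[k] = node
            node = parent[node]
            k += 1
        # reverse in place -> chain[0] = root, chain[k-1] = leaf
        for i in range(k // 2):
            chain[i], chain[k - 1 - i] = chain[k - 1 - i], chain[i]

        # merge per-feature fractions along the path
        m = 0
        for i in range(k - 1):
            node = chain[i]
            child = chain[i + 1]
            z = cover[child] / cover[node]
            hot = children_left[node] if x[feature[node]] <= threshold[node] else children_right[node]
            o = 1.0 if child == hot else 0.0
            f = feature[node]
            found = -1
            for j in range(m):
                if uf[j] == f:
                    found = j
                    break
            if found >= 0:
                uz[found] *= z
                uo[found] *= o
            else:
                uf[m] = f
                uz[m] = z
                uo[m] = o
                m += 1
        if m == 0:
            continue  # root-only path contributes nothing feature-wise

        # EXTEND: dummy entry then each merged feature
        w[0] = 1.0
        length = 0  # index of last entry
        for j in range(m):
            pz = uz[j]
            po = uo[j]
            length += 1
            w[length] = 0.0
            for i in range(length - 1, -1, -1):
                w[i + 1] += po * w[i] * (i + 1.0) / (length + 1.0)
                w[i] = pz * w[i] * (length - i) / (length + 1.0)

        leaf_value = values[leaf]
        # UNWIND each feature and accumulate its attribution
        for j in range(m):
            one = uo[j]
            zero = uz[j]
            next_one = w[length]
            total = 0.0
            for i in range(length - 1, -1, -1):
                if one != 0.0:
                    t = next_one * (length + 1.0) / ((i + 1.0) * one)
                    total += t
                    next_one = w[i] - t * zero * (length - i) / (length + 1.0)
                else:
                    total += w[i] * (length + 1.0) / (zero * (length - i))
            phi[uf[j]] += total * (one - zero) * leaf_value


@njit(cache=True)
def _tree_shap_matrix(
    X, children_left, children_right, feature, threshold, values, cover, Phi
):
    for s in range(X.shape[0]):
        _leaf_shap(
            X[s], children_left, children_right, feature, threshold, values, cover, Phi[s]
        )


def _tree_arrays(tree):
    t = tree.tree_
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.value.reshape(-1).astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
    )


def _as_traversal_dtype(X) -> np.ndarray:
    # sklearn casts inputs to float32 before tree traversal; mirror that so
    # near-threshold rows take the same branch here as in model.predict
    return np.ascontiguousarray(
        np.asarray(X).astype(np.float32).astype(np.float64)
    )


def tree_shap_single(tree, X) -> tuple[np.ndarray, float]:
    """Attributions and base value for one fitted regression tree."""
    X = _as_traversal_dtype(X)
    cl, cr, feat, thr, val, cov = _tree_arrays(tree)
    Phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    _tree_shap_matrix(X, cl, cr, feat, thr, val, cov, Phi)
    return Phi, float(val[0])


def shap_values(model, X) -> tuple[np.ndarray, float]:
    """Exact attributions for a RandomForestRegressor (or one tree).

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features);
    ``base + phi.sum(axis=1)`` equals ``model.predict(X)`` up to float error.
    """
    X = _as_traversal_dtype(X)
    trees = getattr(model, "estimators_", None)
    if trees is None:
        return tree_shap_single(model, X)
    Phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    base = 0.0
    for tree in trees:
        cl, cr, feat, thr, val, cov = _tree_arrays(tree)
        _tree_shap_matrix(X, cl, cr, feat, thr, val, cov, Phi)
        base += val[0]
    return Phi / len(trees), base / len(trees)


# ---------------------------------------------------------------------------
# independent enumeration oracle (verification only)


def _value_given_subset(tree_arrays, x, subset: frozenset, node: int = 0) -> float:
    cl, cr, feat, thr, val, cov = tree_arrays
    if cl[node] < 0:
        return val[node]
    f = feat[node]
    left, right = cl[node], cr[node]
    if f in subset:
        nxt = left if x[f] <= thr[node] else right
        return _value_given_subset(tree_arrays, x, subset, nxt)
    wl = cov[left] / cov[node]
    return wl * _value_given_subset(tree_arrays, x, subset, left) + (1 - wl) * (
        _value_given_subset(tree_arrays, x, subset, right)
    )


def brute_force_shap(tree, x) -> tuple[np.ndarray, float]:
    """Exponential-time Shapley values under the tree-path-dependent value
    function; verification oracle for small trees (<= ~12 distinct features)."""
    arrays = _tree_arrays(tree)
    x = np.asarray(x, dtype=float)
    used = sorted({int(f) for f in arrays[2] if f >= 0})
    M = len(used)
    if M > 16:
        raise ValueError("brute force limited to small trees")
    phi = np.zeros(x.shape[0])
    for i in used:
        others = [f for f in used if f != i]
        for size in range(M):
            weight = factorial(size) * factorial(M - size - 1) / factorial(M)
            for S in combinations(others, size):
                S = frozenset(S)
                gain = _value_given_subset(arrays, x, S | {i}) - _value_given_subset(arrays, x, S)
                phi[i] += weight * gain
    base = _value_given_subset(arrays, x, frozenset())
    return phi, float(base)
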