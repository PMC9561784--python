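"""Exact path-dependent Shapley attribution for sklearn decision-tree
ensembles.

For a tree ensemble the conditional expectation of the prediction given a
feature subset can be read off the tree structure (missing features follow
all branches weighted by training cover).  The polynomial-time algorithm
below pushes subset-permutation weights down every root-leaf path and
recovers, per input, the exact Shapley value of each feature — satisfying
local accuracy: base value + sum of attributions = the tree's prediction.

``brute_shapley_tree`` is an exponential-time oracle that enumerates feature
coalitions explicitly; it exists for validation only.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
from numba import njit


@njit(cache=True)
def _extend(feat_b, zero_b, one_b, w_b, off, ud, pz, po, pi):
    feat_b[off + ud] = pi
    zero_b[off + ud] = pz
    one_b[off + ud] = po
    w_b[off + ud] = 1.0 if ud == 0 else 0.0
    for i in range(ud - 1, -1, -1):
        w_b[off + i + 1] += po * w_b[off + i] * (i + 1.0) / (ud + 1.0)
        w_b[off + i] = pz * w_b[off + i] * (ud - i) / (ud + 1.0)


@njit(cache=True)
def _unwind(feat_b, zero_b, one_b, w_b, off, ud, pidx):
    one = one_b[off + pidx]
    zero = zero_b[off + pidx]
    nxt = w_b[off + ud]
    for i in range(ud - 1, -1, -1):
        if one != 0.0:
            tmp = w_b[off + i]
            w_b[off + i] = nxt * (ud + 1.0) / ((i + 1.0) * one)
            nxt = tmp - w_b[off + i] * zero * (ud - i) / (ud + 1.0)
        else:
            w_b[off + i] = w_b[off + i] * (ud + 1.0) / (zero * (ud - i))
    for i in range(pidx, ud):
        feat_b[off + i] = feat_b[off + i + 1]
        zero_b[off + i] = zero_b[off + i + 1]
        one_b[off + i] = one_b[off + i + 1]


@njit(cache=True)
def _unwound_sum(zero_b, one_b, w_b, off, ud, pidx):
    one = one_b[off + pidx]
    zero = zero_b[off + pidx]
    nxt = w_b[off + ud]
    total = 0.0
    if one != 0.0:
        for i in range(ud - 1, -1, -1):
            tmp = nxt / ((i + 1.0) * one)
            total += tmp
            nxt = w_b[off + i] - tmp * zero * (ud - i)
    else:
        for i in range(ud - 1, -1, -1):
            total += w_b[off + i] / (zero * (ud - i))
    return total * (ud + 1.0)


@njit(cache=True)
def _tree_shap_one(
    left, right, feature, threshold, value, cover, x, phi, max_depth
):
    """Attributions of one tree for one sample, added into ``phi``."""
    size = (max_depth + 2) * (max_depth + 3) // 2 + max_depth + 4
    feat_b = np.empty(size, dtype=np.int64)
    zero_b = np.empty(size, dtype=np.float64)
    one_b = np.empty(size, dtype=np.float64)
    w_b = np.empty(size, dtype=np.float64)
    # DFS stack: node, parent buffer offset, parent path length, pz, po, pi
    cap = 2 * (max_depth + 2)
    st_node = np.empty(cap, dtype=np.int64)
    st_poff = np.empty(cap, dtype=np.int64)
    st_plen = np.empty(cap, dtype=np.int64)
    st_pz = np.empty(cap, dtype=np.float64)
    st_po = np.empty(cap, dtype=np.float64)
    st_pi = np.empty(cap, dtype=np.int64)
    top = 0
    st_node[0] = 0
    st_poff[0] = 0
    st_plen[0] = 0
    st_pz[0] = 1.0
    st_po[0] = 1.0
    st_pi[0] = -1
    top = 1
    while top > 0:
        top -= 1
        node = st_node[top]
        poff = st_poff[top]
        plen = st_plen[top]
        pz = st_pz[top]
        po = st_po[top]
        pi = st_pi[top]
        off = poff + plen + 1
        for i in range(plen):
            feat_b[off + i] = feat_b[poff + i]
            zero_b[off + i] = zero_b[poff + i]
            one_b[off + i] = one_b[poff + i]
            w_b[off + i] = w_b[poff + i]
        ud = plen
        _extend(feat_b, zero_b, one_b, w_b, off, ud, pz, po, pi)
        if left[node] < 0:  # leaf
            for i in range(1, ud + 1):
                w = _unwound_sum(zero_b, one_b, w_b, off, ud, i)
                phi[feat_b[off + i]] += (
                    w * (one_b[off + i] - zero_b[off + i]) * value[node]
                )
        else:
            f = feature[node]
            if x[f] <= threshold[node]:
                hot, cold = left[node], right[node]
            else:
                hot, cold = right[node], left[node]
            hot_zero = cover[hot] / cover[node]
            cold_zero = cover[cold] / cover[node]
            iz = 1.0
            io = 1.0
            pidx = -1
            for i in range(ud + 1):
                if feat_b[off + i] == f:
                    pidx = i
                    break
            if pidx >= 0:
                iz = zero_b[off + pidx]
                io = one_b[off + pidx]
                _unwind(feat_b, zero_b, one_b, w_b, off, ud, pidx)
                ud -= 1
            # push cold then hot (processing order irrelevant)
            st_node[top] = cold
            st_poff[top] = off
            st_plen[top] = ud + 1
            st_pz[top] = cold_zero * iz
            st_po[top] = 0.0
            st_pi[top] = f
            top += 1
            st_node[top] = hot
            st_poff[top] = off
            st_plen[top] = ud + 1
            st_pz[top] = hot_zero * iz
            st_po[top] = io
            st_pi[top] = f
            top += 1


def _tree_arrays(tree):
    """(left, right, feature, threshold, leaf prob of class 1, cover)."""
    t = tree.tree_
    value = t.value[:, 0, :]
    totals = value.sum(axis=1)
    prob1 = value[:, -1] / np.where(totals > 0, totals, 1.0)
    if value.shape[1] == 1:  # single-class tree
        prob1 = value[:, 0] / np.where(totals > 0, totals, 1.0)
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        prob1.astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def tree_expected_value(tree) -> float:
    """Cover-weighted mean leaf prediction (probability of the last class)."""
    left, right, feature, threshold, prob1, cover, _ = _tree_arrays(tree)
    leaves = left < 0
    return float(np.sum(prob1[leaves] * cover[leaves]) / cover[0])


def forest_shap_values(forest, X) -> tuple[np.ndarray, float]:
    """Exact Shapley attributions of a fitted forest's printable-class
    probability for every row of ``X``.

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features);
    ``base + phi.sum(1)`` equals ``forest.predict_proba(X)[:, -1]`` up to
    floating-point round-off.
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    phi = np.zeros((n, p))
    base = 0.0
    trees = forest.estimators_
    for est in trees:
        left, right, feature, threshold, prob1, cover, maxd = _tree_arrays(est)
        base += np.sum(prob1[left < 0] * cover[left < 0]) / cover[0]
        for i in range(n):
            _tree_shap_one(
                left, right, feature, threshold, prob1, cover, X[i], phi[i], maxd
            )
    phi /= len(trees)
    base /= len(trees)
    return phi, float(base)


# ---------------------------------------------------------------------------
# exhaustive-coalition oracle (validation only)


def _cond_expectation(tree_arrays, x, subset: frozenset) -> float:
    left, right, feature, threshold, prob1, cover, _ = tree_arrays

    def rec(node: int) -> float:
        if left[node] < 0:
            return prob1[node]
        f = feature[node]
        if f in subset:
            child = left[node] if x[f] <= threshold[node] else right[node]
            return rec(child)
        wl = cover[left[node]] / cover[node]
        wr = cover[right[node]] / cover[node]
        return wl * rec(left[node]) + wr * rec(right[node])

    return rec(0)


def brute_shapley_tree(tree, x, n_features: int) -> np.ndarray:
    """Exact Shapley values of one tree by explicit coalition enumeration.

    Exponential in the number of features actually used by the tree; meant
    for tiny validation trees only.
    """
    arrays = _tree_arrays(tree)
    used = sorted(set(arrays[2][arrays[2] >= 0].tolist()))
    d = len(used)
    phi = np.zeros(n_features)
    x = np.asarray(x, dtype=float)
    for j in used:
        others = [f for f in used if f != j]
        for r in range(d):
            for T in combinations(others, r):
                w = factorial(r) * factorial(d - r - 1) / factorial(d)
                vT = _cond_expectation(arrays, x, frozenset(T))
                vTj = _cond_expectation(arrays, x, frozenset(T) | {j})
                phi[j] += w * (vTj - vT)
    return phi
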