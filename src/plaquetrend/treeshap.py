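"""Exact SHAP attributions for gradient-boosted tree ensembles, in float64.

Implements the path-dependent TreeSHAP recursion over the fitted booster's
dumped trees, with all arithmetic in double precision so that the additive
decomposition  prediction = base_value + Σ_i φ_i  holds to numerical
round-off.  The conditional expectation E[f(x) | x_S] is estimated the way
the trees themselves weight their branches: by the training cover (hessian
sum) of each child.

The module also evaluates the ensemble margin in float64
(:func:`predict_margin`), which is the quantity the attributions decompose
exactly; the booster's own float32 prediction agrees with it to single
precision.
"""

from __future__ import annotations

import json

import numpy as np
from numba import njit

__all__ = ["TreeEnsemble", "shap_values", "predict_margin"]


class TreeEnsemble:
    """Array representation of an XGBoost booster's trees."""

    def __init__(self, booster):
        df = booster.trees_to_dataframe()
        feature_names = booster.feature_names
        self.n_features = (
            len(feature_names) if feature_names is not None else booster.num_features()
        )
        cfg = json.loads(booster.save_config())
        self.base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
        self.trees = []
        for _, g in df.groupby("Tree", sort=True):
            g = g.sort_values("Node")
            n = len(g)
            node_of = {node_id: i for i, node_id in enumerate(g["ID"])}
            cl = np.full(n, -1, dtype=np.int64)
            cr = np.full(n, -1, dtype=np.int64)
            cd = np.full(n, -1, dtype=np.int64)
            feat = np.zeros(n, dtype=np.int64)
            thr = np.zeros(n, dtype=np.float64)
            val = np.zeros(n, dtype=np.float64)
            cov = np.zeros(n, dtype=np.float64)
            for i, row in enumerate(g.itertuples(index=False)):
                cov[i] = row.Cover
                if row.Feature == "Leaf":
                    val[i] = row.Gain  # leaf value is reported in the Gain column
                else:
                    cl[i] = node_of[row.Yes]
                    cr[i] = node_of[row.No]
                    cd[i] = node_of[row.Missing]
                    if feature_names is not None:
                        feat[i] = feature_names.index(row.Feature)
                    else:
                        feat[i] = int(str(row.Feature).lstrip("f"))
                    # the dump prints thresholds in decimal; round-trip through
                    # float32 to recover the exact stored split value
                    thr[i] = float(np.float32(row.Split))
            self.trees.append((cl, cr, cd, feat, thr, val, cov))

    def max_depth(self) -> int:
        def depth(tree, node=0):
            cl = tree[0]
            if cl[node] < 0:
                return 0
            return 1 + max(depth(tree, tree[0][node]), depth(tree, tree[1][node]))

        return max(depth(t) for t in self.trees)


def _as_f32_exact(X) -> np.ndarray:
    # XGBoost evaluates split conditions in float32; routing must match it,
    # so inputs are rounded through float32 before the float64 descent
    return np.ascontiguousarray(np.asarray(X).astype(np.float32).astype(np.float64))


@njit(cache=False)
def _descend(cl, cr, cd, feat, thr, x, node):
    while cl[node] >= 0:
        v = x[feat[node]]
        if np.isnan(v):
            node = cd[node]
        elif v < thr[node]:
            node = cl[node]
        else:
            node = cr[node]
    return node


@njit(cache=False)
def _expected(cl, cr, val, cov, node):
    if cl[node] < 0:
        return val[node]
    left = _expected(cl, cr, val, cov, cl[node])
    right = _expected(cl, cr, val, cov, cr[node])
    return (cov[cl[node]] * left + cov[cr[node]] * right) / cov[node]


@njit(cache=False)
def _unwound_sum(pz, po, pw, unique_depth, path_index):
    one = po[path_index]
    zero = pz[path_index]
    next_one = pw[unique_depth]
    total = 0.0
    if one != 0.0:
        for i in range(unique_depth - 1, -1, -1):
            tmp = next_one / ((i + 1) * one)
            total += tmp
            next_one = pw[i] - tmp * zero * (unique_depth - i)
    else:
        for i in range(unique_depth - 1, -1, -1):
            total += pw[i] / (zero * (unique_depth - i))
    return total * (unique_depth + 1)


@njit(cache=False)
def _extend(pd, pz, po, pw, offset, unique_depth, pzf, pof, pif):
    pd[offset + unique_depth] = pif
    pz[offset + unique_depth] = pzf
    po[offset + unique_depth] = pof
    pw[offset + unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[offset + i + 1] += pof * pw[offset + i] * (i + 1) / (unique_depth + 1)
        pw[offset + i] = pzf * pw[offset + i] * (unique_depth - i) / (unique_depth + 1)


@njit(cache=False)
def _unwind(pd, pz, po, pw, offset, unique_depth, path_index):
    one = po[offset + path_index]
    zero = pz[offset + path_index]
    next_one = pw[offset + unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one != 0.0:
            tmp = pw[offset + i]
            pw[offset + i] = next_one * (unique_depth + 1) / ((i + 1) * one)
            next_one = tmp - pw[offset + i] * zero * (unique_depth - i) / (unique_depth + 1)
        else:
            pw[offset + i] = pw[offset + i] * (unique_depth + 1) / (zero * (unique_depth - i))
    for i in range(path_index, unique_depth):
        pd[offset + i] = pd[offset + i + 1]
        pz[offset + i] = pz[offset + i + 1]
        po[offset + i] = po[offset + i + 1]


@njit(cache=False)
def _tree_shap(cl, cr, cd, feat, thr, val, cov, x, phi, node, unique_depth, offset,
               pd, pz, po, pw, pzf, pof, pif):
    new = offset + unique_depth + 1
    for i in range(unique_depth):
        pd[new + i] = pd[offset + i]
        pz[new + i] = pz[offset + i]
        po[new + i] = po[offset + i]
        pw[new + i] = pw[offset + i]
    _extend(pd, pz, po, pw, new, unique_depth, pzf, pof, pif)
    if cl[node] < 0:  # leaf
        for i in range(1, unique_depth + 1):
            w = _unwound_sum(pz[new:], po[new:], pw[new:], unique_depth, i)
            phi[pd[new + i]] += w * (po[new + i] - pz[new + i]) * val[node]
        return
    v = x[feat[node]]
    if np.isnan(v):
        hot = cd[node]
    elif v < thr[node]:
        hot = cl[node]
    else:
        hot = cr[node]
    cold = cr[node] if hot == cl[node] else cl[node]
    inc_zero = 1.0
    inc_one = 1.0
    depth_here = unique_depth
    path_index = 0
    found = False
    for i in range(unique_depth + 1):
        if pd[new + i] == feat[node]:
            path_index = i
            found = True
            break
    if found:
        inc_zero = pz[new + path_index]
        inc_one = po[new + path_index]
        _unwind(pd, pz, po, pw, new, depth_here, path_index)
        depth_here -= 1
    hot_zero = cov[hot] / cov[node]
    cold_zero = cov[cold] / cov[node]
    _tree_shap(cl, cr, cd, feat, thr, val, cov, x, phi, hot, depth_here + 1, new,
               pd, pz, po, pw, hot_zero * inc_zero, inc_one, feat[node])
    _tree_shap(cl, cr, cd, feat, thr, val, cov, x, phi, cold, depth_here + 1, new,
               pd, pz, po, pw, cold_zero * inc_zero, 0.0, feat[node])


def shap_values(ensemble: TreeEnsemble, X) -> tuple:
    """Per-sample per-feature SHAP values and the ensemble base value.

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features);
    ``phi.sum(axis=1) + base`` equals :func:`predict_margin` to float64
    round-off.
    """
    X = _as_f32_exact(X)
    n, _ = X.shape
    phi = np.zeros((n, ensemble.n_features), dtype=np.float64)
    depth = ensemble.max_depth() + 2
    size = (depth + 1) * (depth + 2) // 2 + depth + 2
    pd = np.zeros(size, dtype=np.int64)
    pz = np.zeros(size, dtype=np.float64)
    po = np.zeros(size, dtype=np.float64)
    pw = np.zeros(size, dtype=np.float64)
    for cl, cr, cdn, feat, thr, val, cov in ensemble.trees:
        for i in range(n):
            _tree_shap(cl, cr, cdn, feat, thr, val, cov, X[i], phi[i], 0, 0, -1,
                       pd, pz, po, pw, 1.0, 1.0, -1)
    base = ensemble.base_score + sum(
        _expected(t[0], t[1], t[5], t[6], 0) for t in ensemble.trees
    )
    return phi, float(base)


def predict_margin(ensemble: TreeEnsemble, X) -> np.ndarray:
    """Float64 margin prediction of the ensemble (base score + leaf sums)."""
    X = _as_f32_exact(X)
    out = np.full(X.shape[0], ensemble.base_score, dtype=np.float64)
    for cl, cr, cdn, feat, thr, val, cov in ensemble.trees:
        for i in range(X.shape[0]):
            out[i] += val[_descend(cl, cr, cdn, feat, thr, X[i], 0)]
    return out
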