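"""Regularized random forest regression.

A random forest of CART regression trees (variance-reduction splitting,
bootstrap resampling, per-node random feature subsets) with guided
regularization: the split gain of a feature that no tree in the ensemble
has used yet is multiplied by a penalty ``gamma`` in (0, 1].  Trees are
therefore grown sequentially, and later trees are steered toward the
feature set discovered by earlier ones.  ``gamma = 1`` recovers a plain
random forest.

The tree builder is numba-compiled; at the sample sizes this package
targets (tens to a few hundred samples, tens to hundreds of features) a
10,000-tree forest trains in seconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["RegularizedRandomForest"]

_LEAF = -1


@njit(cache=True)
def _grow_tree(
    X,
    y,
    sample_idx,
    mtry,
    min_node_size,
    gamma,
    used,
    seed,
    feature_out,
    threshold_out,
    left_out,
    right_out,
    value_out,
):
    """Grow one CART regression tree; returns the number of nodes.

    ``used`` is the ensemble-level mask of features already chosen by any
    previous tree; it is updated in place with this tree's choices.
    """
    np.random.seed(seed)
    n_total = sample_idx.shape[0]
    p = X.shape[1]

    # explicit stack of (node_id, start, end) over a reorderable index buffer
    idx = sample_idx.copy()
    max_nodes = feature_out.shape[0]
    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    n_nodes = 1
    top = 0
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n_total
    feat_pool = np.empty(p, np.int64)

    while top >= 0:
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        top -= 1
        n_node = hi - lo

        y_sum = 0.0
        for i in range(lo, hi):
            y_sum += y[idx[i]]
        node_mean = y_sum / n_node
        value_out[node] = node_mean
        feature_out[node] = _LEAF
        left_out[node] = _LEAF
        right_out[node] = _LEAF

        if n_node <= min_node_size or n_nodes + 2 > max_nodes:
            continue

        # draw mtry candidate features without replacement (partial Fisher-Yates)
        for j in range(p):
            feat_pool[j] = j
        best_gain = 0.0
        best_feat = -1
        best_thr = 0.0
        for t in range(mtry):
            r = t + np.random.randint(p - t)
            tmp = feat_pool[t]
            feat_pool[t] = feat_pool[r]
            feat_pool[r] = tmp
            f = feat_pool[t]

            # sort node samples by feature f (insertion sort on small nodes
            # is fine; use argsort on the extracted column)
            col = np.empty(n_node, np.float64)
            yv = np.empty(n_node, np.float64)
            for i in range(n_node):
                col[i] = X[idx[lo + i], f]
            order = np.argsort(col, kind="mergesort")
            for i in range(n_node):
                yv[i] = y[idx[lo + order[i]]]

            # prefix scan for best variance-reduction split
            total_sum = y_sum
            penalty = 1.0 if used[f] else gamma
            left_sum = 0.0
            for i in range(n_node - 1):
                left_sum += yv[i]
                xi = col[order[i]]
                xj = col[order[i + 1]]
                if xi == xj:
                    continue
                nl = i + 1
                nr = n_node - nl
                right_sum = total_sum - left_sum
                # gain = reduction in total sum of squares
                gain = (
                    left_sum * left_sum / nl
                    + right_sum * right_sum / nr
                    - total_sum * total_sum / n_node
                )
                pgain = gain * penalty
                if pgain > best_gain + 1e-12:
                    best_gain = pgain
                    best_feat = f
                    best_thr = 0.5 * (xi + xj)

        if best_feat < 0:
            continue

        # partition idx[lo:hi] around the threshold
        i = lo
        j = hi - 1
        while i <= j:
            if X[idx[i], best_feat] <= best_thr:
                i += 1
            else:
                tmp2 = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp2
                j -= 1
        mid = i
        if mid == lo or mid == hi:
            continue  # degenerate partition (should not happen)

        used[best_feat] = True
        feature_out[node] = best_feat
        threshold_out[node] = best_thr
        lc = n_nodes
        rc = n_nodes + 1
        n_nodes += 2
        left_out[node] = lc
        right_out[node] = rc
        top += 1
        stack_node[top] = lc
        stack_lo[top] = lo
        stack_hi[top] = mid
        top += 1
        stack_node[top] = rc
        stack_lo[top] = mid
        stack_hi[top] = hi

    return n_nodes


@njit(cache=True)
def _predict_forest(X, features, thresholds, lefts, rights, values, offsets, out):
    n = X.shape[0]
    n_trees = offsets.shape[0] - 1
    for i in range(n):
        acc = 0.0
        for t in range(n_trees):
            base = offsets[t]
            node = 0
            while features[base + node] != _LEAF:
                if X[i, features[base + node]] <= thresholds[base + node]:
                    node = lefts[base + node]
                else:
                    node = rights[base + node]
            acc += values[base + node]
        out[i] = acc / n_trees


class RegularizedRandomForest:
    """Random forest regressor with RRF-style guided regularization.

    Parameters
    ----------
    n_trees : int
        Number of trees, grown sequentially.
    gamma : float in (0, 1]
        Split-gain multiplier for features not yet used by the ensemble.
        1.0 disables regularization (plain random forest).
    mtry : int or None
        Features tried per split; defaults to ``max(p // 3, 1)``, the
        customary regression default.
    min_node_size : int
        Nodes at or below this size are not split further (the R
        randomForest ``nodesize`` convention; children may be smaller).
    seed : int
        Seed for bootstrap resampling and feature subsampling.
    """

    def __init__(
        self,
        n_trees: int = 10_000,
        gamma: float = 0.8,
        mtry: int | None = None,
        min_node_size: int = 5,
        seed: int = 0,
    ):
        if not (0.0 < gamma <= 1.0):
            raise ValueError(f"gamma must be in (0, 1], got {gamma}")
        if n_trees < 1:
            raise ValueError("n_trees must be positive")
        self.n_trees = int(n_trees)
        self.gamma = float(gamma)
        self.mtry = mtry
        self.min_node_size = int(min_node_size)
        self.seed = int(seed)
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegularizedRandomForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, p) and y (n,) with matching n")
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least two training samples")
        if np.unique(y).size < 2:
            import warnings

            warnings.warn("training response is constant; forest predicts a constant")
        mtry = self.mtry if self.mtry is not None else max(p // 3, 1)
        mtry = min(mtry, p)

        rng = np.random.default_rng(self.seed)
        max_nodes = 2 * n + 1
        used = np.zeros(p, dtype=np.bool_)
        feats, thrs, lefts, rights, vals = [], [], [], [], []
        offsets = np.zeros(self.n_trees + 1, dtype=np.int64)
        fo = np.empty(max_nodes, np.int64)
        to = np.empty(max_nodes, np.float64)
        lo = np.empty(max_nodes, np.int64)
        ro = np.empty(max_nodes, np.int64)
        vo = np.empty(max_nodes, np.float64)
        for t in range(self.n_trees):
            boot = rng.integers(0, n, size=n).astype(np.int64)
            tree_seed = int(rng.integers(0, 2**31 - 1))
            n_nodes = _grow_tree(
                X,
                y,
                boot,
                mtry,
                self.min_node_size,
                self.gamma,
                used,
                tree_seed,
                fo,
                to,
                lo,
                ro,
                vo,
            )
            feats.append(fo[:n_nodes].copy())
            thrs.append(to[:n_nodes].copy())
            lefts.append(lo[:n_nodes].copy())
            rights.append(ro[:n_nodes].copy())
            vals.append(vo[:n_nodes].copy())
            offsets[t + 1] = offsets[t] + n_nodes

        self._features = np.concatenate(feats)
        self._thresholds = np.concatenate(thrs)
        self._lefts = np.concatenate(lefts)
        self._rights = np.concatenate(rights)
        self._values = np.concatenate(vals)
        self._offsets = offsets
        self.feature_used_ = used
        self.n_features_in_ = p
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("forest is not fitted")
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} features, got shape {X.shape}"
            )
        out = np.empty(X.shape[0], dtype=np.float64)
        _predict_forest(
            X,
            self._features,
            self._thresholds,
            self._lefts,
            self._rights,
            self._values,
            self._offsets,
            out,
        )
        return out
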