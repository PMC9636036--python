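"""Minimal extremely-randomized-trees classifier, numba-jitted.

The Monte Carlo combination search refits a small tree ensemble tens of
thousands of times on cohorts of ~100 samples and <=10 features; a compact
jitted implementation keeps each fit in the sub-millisecond range on one
CPU.  The algorithm is the standard extra-trees recipe: at each node, K
randomly chosen features each receive one uniformly random cut point
between the node's min and max, the best of the K by Gini impurity wins,
and nodes split until pure.  No bootstrap; leaves store the class-1
fraction, predictions average leaf values over trees.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _forest_predict(Xtr, ytr, Xte, n_trees, k_features, seed):
    n, p = Xtr.shape
    n_te = Xte.shape[0]
    out = np.zeros(n_te)
    max_nodes = 2 * n + 1
    feat = np.empty(max_nodes, np.int64)
    thr = np.empty(max_nodes)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    val = np.empty(max_nodes)
    stack_node = np.empty(max_nodes, np.int64)
    stack_s = np.empty(max_nodes, np.int64)
    stack_e = np.empty(max_nodes, np.int64)
    Xw = np.empty((n, p))
    yw = np.empty(n)
    np.random.seed(seed)
    for _ in range(n_trees):
        for i in range(n):
            for j in range(p):
                Xw[i, j] = Xtr[i, j]
            yw[i] = ytr[i]
        n_nodes = 1
        top = 0
        stack_node[0] = 0; stack_s[0] = 0; stack_e[0] = n
        while top >= 0:
            node = stack_node[top]; s = stack_s[top]; e = stack_e[top]; top -= 1
            m = e - s
            pos = 0.0
            for i in range(s, e):
                pos += yw[i]
            if m < 2 or pos == 0.0 or pos == m:
                feat[node] = -1; val[node] = pos / m
                continue
            best_score = 1e30; best_f = -1; best_thr = 0.0
            for _k in range(k_features):
                f = np.random.randint(0, p)
                fmin = Xw[s, f]; fmax = fmin
                for i in range(s + 1, e):
                    v = Xw[i, f]
                    if v < fmin: fmin = v
                    elif v > fmax: fmax = v
                if fmax <= fmin: continue
                t = fmin + np.random.random() * (fmax - fmin)
                if t <= fmin: continue
                nl = 0; pl = 0.0
                for i in range(s, e):
                    if Xw[i, f] < t:
                        nl += 1; pl += yw[i]
                nr = m - nl
                if nl == 0 or nr == 0: continue
                pr = pos - pl
                ql = pl / nl; qr = pr / nr
                score = nl * ql * (1.0 - ql) + nr * qr * (1.0 - qr)
                if score < best_score:
                    best_score = score; best_f = f; best_thr = t
            if best_f < 0:
                feat[node] = -1; val[node] = pos / m
                continue
            i = s; j = e - 1
            while i <= j:
                if Xw[i, best_f] < best_thr:
                    i += 1
                else:
                    for c in range(p):
                        tmp = Xw[i, c]; Xw[i, c] = Xw[j, c]; Xw[j, c] = tmp
                    tmpy = yw[i]; yw[i] = yw[j]; yw[j] = tmpy
                    j -= 1
            mid = i
            feat[node] = best_f; thr[node] = best_thr
            lc = n_nodes; rc = n_nodes + 1; n_nodes += 2
            left[node] = lc; right[node] = rc
            top += 1; stack_node[top] = lc; stack_s[top] = s; stack_e[top] = mid
            top += 1; stack_node[top] = rc; stack_s[top] = mid; stack_e[top] = e
        for i in range(n_te):
            node = 0
            while feat[node] >= 0:
                if Xte[i, feat[node]] < thr[node]: node = left[node]
                else: node = right[node]
            out[i] += val[node]
    return out / n_trees


class FastExtraTrees:
    """Extra-trees binary classifier with a fit-and-score call.

    Parameters mirror the sklearn estimator where they exist: number of
    trees, features tried per split (default ceil(sqrt(p))), random seed.
    """

    def __init__(self, n_estimators: int = 100, max_features: int | None = None,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit_predict_proba(self, X_train, y_train, X_test) -> np.ndarray:
        """Fit on the training set and return class-1 probabilities on the
        test set (single fused call; nothing is retained)."""
        Xtr = np.ascontiguousarray(X_train, dtype=np.float64)
        Xte = np.ascontiguousarray(X_test, dtype=np.float64)
        ytr = np.ascontiguousarray(y_train, dtype=np.float64)
        p = Xtr.shape[1]
        k = self.max_features or max(1, int(np.ceil(np.sqrt(p))))
        return _forest_predict(
            Xtr, ytr, Xte, self.n_estimators, min(k, p),
            int(self.random_state) % (2**31 - 1),
        )
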