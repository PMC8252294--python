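"""A compact CART random-forest classifier compiled with numba.

The permutation-null selection procedure fits thousands of 1000-tree forests
on tiny tables (tens of samples, ~80 features), a regime where general-purpose
implementations pay per-tree orchestration costs far exceeding the tree
building itself.  This engine keeps the standard algorithm — bootstrap
resampling (n-of-n with replacement), exhaustive Gini splits over a fresh
sqrt(p)-sized feature draw at every node (constant features trigger a redraw,
so a node is only left unsplit when no feature separates it), growth until
purity — and reports mean decrease in impurity feature importances with the
usual normalisation: per-tree importances are scaled to sum to one, averaged
over trees that split at least once, and renormalised.  Class probabilities
are tree-averaged leaf frequencies.

Statistical equivalence to ``sklearn.ensemble.RandomForestClassifier`` is
asserted in the test suite, and that implementation remains available as an
alternative engine in :mod:`trichoselect.selection`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fit_forest", "NativeForestClassifier"]

_MAX_NODES_FACTOR = 4  # nodes <= 2*n_leaves - 1 <= 2n; headroom for safety


@njit(cache=True)
def _build_and_apply(X, y, X_test, n_classes, n_trees, mtry, seeds):
    """Fit a forest on (X, y); return (importances, test class-prob sums, n_split_trees).

    X: (n, p) float32, y: (n,) int8, X_test: (m, p) float32 (m may be 0).
    """
    n, p = X.shape
    m = X_test.shape[0]
    max_nodes = _MAX_NODES_FACTOR * n + 8

    feat = np.empty(max_nodes, dtype=np.int64)
    thresh = np.empty(max_nodes, dtype=np.float32)
    left = np.empty(max_nodes, dtype=np.int64)
    right = np.empty(max_nodes, dtype=np.int64)
    value = np.empty((max_nodes, n_classes), dtype=np.float64)

    # explicit DFS stack over [start, end) ranges of the bootstrap index buffer
    stack_start = np.empty(max_nodes, dtype=np.int64)
    stack_end = np.empty(max_nodes, dtype=np.int64)
    stack_parent = np.empty(max_nodes, dtype=np.int64)
    stack_isleft = np.empty(max_nodes, dtype=np.int64)

    samples = np.empty(n, dtype=np.int64)
    counts = np.empty(n_classes, dtype=np.int64)
    left_counts = np.empty(n_classes, dtype=np.int64)
    best_left_counts = np.empty(n_classes, dtype=np.int64)
    vals = np.empty(n, dtype=np.float32)
    order = np.empty(n, dtype=np.int64)
    perm = np.empty(p, dtype=np.int64)

    importances = np.zeros(p, dtype=np.float64)
    tree_importance = np.empty(p, dtype=np.float64)
    prob_sum = np.zeros((m, n_classes), dtype=np.float64)
    n_split_trees = 0

    for t in range(n_trees):
        np.random.seed(seeds[t])
        # bootstrap sample
        for i in range(n):
            samples[i] = np.random.randint(0, n)
        for j in range(p):
            tree_importance[j] = 0.0

        n_nodes = 0
        top = 0
        stack_start[0] = 0
        stack_end[0] = n
        stack_parent[0] = -1
        stack_isleft[0] = 0
        top = 1
        tree_split = False

        while top > 0:
            top -= 1
            start = stack_start[top]
            end = stack_end[top]
            parent = stack_parent[top]
            isleft = stack_isleft[top]

            node = n_nodes
            n_nodes += 1
            if parent >= 0:
                if isleft == 1:
                    left[parent] = node
                else:
                    right[parent] = node

            nn = end - start
            for c in range(n_classes):
                counts[c] = 0
            for i in range(start, end):
                counts[y[samples[i]]] += 1
            for c in range(n_classes):
                value[node, c] = counts[c] / nn

            # Gini impurity of the node
            gini = 1.0
            pure = False
            for c in range(n_classes):
                fr = counts[c] / nn
                gini -= fr * fr
                if counts[c] == nn:
                    pure = True

            feat[node] = -1
            left[node] = -1
            right[node] = -1

            if pure or nn < 2:
                continue

            # draw features without replacement; keep drawing past mtry while
            # only constant features have been seen (sklearn-style redraw)
            for j in range(p):
                perm[j] = j
            best_improve = 0.0
            best_feat = -1
            best_thresh = np.float32(0.0)
            n_evaluated = 0
            drawn = 0
            while drawn < p and (n_evaluated < mtry or best_feat == -1):
                r = drawn + np.random.randint(0, p - drawn)
                tmp = perm[drawn]
                perm[drawn] = perm[r]
                perm[r] = tmp
                f = perm[drawn]
                drawn += 1

                # gather + insertion sort (node sizes are tiny)
                for i in range(nn):
                    vals[i] = X[samples[start + i], f]
                    order[i] = start + i
                for i in range(1, nn):
                    v = vals[i]
                    o = order[i]
                    j2 = i - 1
                    while j2 >= 0 and vals[j2] > v:
                        vals[j2 + 1] = vals[j2]
                        order[j2 + 1] = order[j2]
                        j2 -= 1
                    vals[j2 + 1] = v
                    order[j2 + 1] = o
                if vals[nn - 1] <= vals[0]:
                    continue  # constant feature: does not count toward mtry
                n_evaluated += 1

                for c in range(n_classes):
                    left_counts[c] = 0
                for i in range(nn - 1):
                    left_counts[y[samples[order[i]]]] += 1
                    if vals[i + 1] <= vals[i]:
                        continue
                    nl = i + 1
                    nr = nn - nl
                    gl = 1.0
                    gr = 1.0
                    for c in range(n_classes):
                        fl = left_counts[c] / nl
                        frc = (counts[c] - left_counts[c]) / nr
                        gl -= fl * fl
                        gr -= frc * frc
                    improve = gini - (nl * gl + nr * gr) / nn
                    if improve > best_improve + 1e-12:
                        best_improve = improve
                        best_feat = f
                        best_thresh = np.float32(0.5 * (vals[i] + vals[i + 1]))
                        for c in range(n_classes):
                            best_left_counts[c] = left_counts[c]

            if best_feat == -1:
                continue  # no separating feature: impure leaf

            # mean-decrease-in-impurity contribution, weighted by node share
            tree_importance[best_feat] += (nn / n) * best_improve
            tree_split = True

            # partition samples[start:end] in place
            i = start
            j3 = end - 1
            while i <= j3:
                if X[samples[i], best_feat] <= best_thresh:
                    i += 1
                else:
                    tmp2 = samples[i]
                    samples[i] = samples[j3]
                    samples[j3] = tmp2
                    j3 -= 1
            split_at = i
            feat[node] = best_feat
            thresh[node] = best_thresh

            # push right then left so the left child is processed first
            stack_start[top] = split_at
            stack_end[top] = end
            stack_parent[top] = node
            stack_isleft[top] = 0
            top += 1
            stack_start[top] = start
            stack_end[top] = split_at
            stack_parent[top] = node
            stack_isleft[top] = 1
            top += 1

        if tree_split:
            n_split_trees += 1
            s = 0.0
            for j in range(p):
                s += tree_importance[j]
            for j in range(p):
                importances[j] += tree_importance[j] / s

        # accumulate test-set leaf frequencies
        for q in range(m):
            node = 0
            while feat[node] >= 0:
                if X_test[q, feat[node]] <= thresh[node]:
                    node = left[node]
                else:
                    node = right[node]
            for c in range(n_classes):
                prob_sum[q, c] += value[node, c]

    return importances, prob_sum, n_split_trees


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    X_test: np.ndarray | None = None,
    *,
    n_trees: int = 1000,
    max_features: int | None = None,
    random_state: int | np.random.SeedSequence = 0,
):
    """Fit a forest; return (importances, test probabilities or None).

    ``max_features`` defaults to ``max(1, round(sqrt(p)))``.  Importances are
    normalised to sum to 1 when at least one split occurred anywhere, all-zero
    otherwise.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    classes, y_enc = np.unique(np.asarray(y), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    y_enc = y_enc.astype(np.int8)
    n, p = X.shape
    mtry = max_features if max_features is not None else max(1, round(np.sqrt(p)))
    mtry = min(mtry, p)
    if isinstance(random_state, np.random.SeedSequence):
        ss = random_state
    else:
        ss = np.random.SeedSequence(int(random_state))
    seeds = ss.generate_state(n_trees, dtype=np.uint32)
    Xt = (
        np.ascontiguousarray(X_test, dtype=np.float32)
        if X_test is not None
        else np.empty((0, p), dtype=np.float32)
    )
    imp, prob_sum, n_split = _build_and_apply(
        X, y_enc, Xt, int(len(classes)), int(n_trees), int(mtry), seeds
    )
    if n_split > 0:
        imp = imp / imp.sum()
    proba = prob_sum / n_trees if X_test is not None else None
    return imp, (proba, classes) if X_test is not None else None


class NativeForestClassifier:
    """Thin sklearn-like facade over :func:`fit_forest` (fit + predict in one pass)."""

    def __init__(self, n_estimators: int = 1000, max_features: int | None = None,
                 random_state: int | np.random.SeedSequence = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit_predict_importances(self, X, y, X_test):
        imp, pred = fit_forest(
            X, y, X_test,
            n_trees=self.n_estimators,
            max_features=self.max_features,
            random_state=self.random_state,
        )
        proba, classes = pred
        y_hat = classes[np.argmax(proba, axis=1)]
        return imp, y_hat
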