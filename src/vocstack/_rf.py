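"""Shared random-forest and ordination primitives.

OOB proximity follows the Breiman definition: the fraction of trees in
which two samples land in the same terminal leaf, counted only over trees
where both samples are out of the bootstrap.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier


def fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int,
               **kwargs) -> RandomForestClassifier:
    model = RandomForestClassifier(
        n_estimators=int(n_trees), random_state=int(seed) & 0x7FFFFFFF,
        n_jobs=1, **kwargs)
    model.fit(X, y)
    return model


def oob_proximity(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Symmetric n × n OOB proximity matrix with unit diagonal.

    Pairs never jointly out of bag get proximity 0 (rare at usual tree
    counts)."""
    n = X.shape[0]
    leaves = model.apply(X)                      # (n, T)
    T = leaves.shape[1]
    oob = np.ones((n, T), dtype=bool)
    for t, sampled in enumerate(model.estimators_samples_):
        oob[np.unique(sampled), t] = False
    co = np.zeros((n, n))
    denom = np.zeros((n, n))
    for t in range(T):
        idx = np.flatnonzero(oob[:, t])
        if idx.size < 2:
            continue
        lv = leaves[idx, t]
        same = (lv[:, None] == lv[None, :]).astype(float)
        co[np.ix_(idx, idx)] += same
        denom[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore"):
        P = np.where(denom > 0, co / np.maximum(denom, 1.0), 0.0)
    P = np.clip((P + P.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(P, 1.0)
    return P


def pcoa(distance: np.ndarray, n_components: int | None = None
         ) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinate analysis of a distance matrix.

    Gower-centers -0.5 * J D^2 J, eigendecomposes, truncates negative
    eigenvalues to zero (the input need not be Euclidean), and returns
    (coordinates, eigenvalues) sorted by decreasing eigenvalue.  The
    returned coordinates span all positive-eigenvalue axes unless
    ``n_components`` caps them.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ (D ** 2) @ J
    G = (G + G.T) / 2.0
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0.0, None)
    pos = w > max(w.max(), 1.0) * 1e-12 if w.size else np.array([], bool)
    k = int(pos.sum())
    if n_components is not None:
        k = min(k, int(n_components))
    coords = V[:, :k] * np.sqrt(w[:k])
    return coords, w


def gower_center(distance: np.ndarray) -> np.ndarray:
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ (D ** 2) @ J
    return (G + G.T) / 2.0


def permutation_importance_fast(model, X_val: np.ndarray, y_val: np.ndarray,
                                rng: np.random.Generator,
                                max_chunk_bytes: int = 2 ** 27) -> np.ndarray:
    """Single-pass permutation importance (mean decrease in accuracy).

    Builds, for each column, a copy of the validation matrix with that
    column permuted, stacks the copies and predicts them in a few large
    batched calls — orders of magnitude faster than per-column predict
    loops at thousands of ratio columns.
    """
    n, p = X_val.shape
    base = float((model.predict(X_val) == y_val).mean())
    imp = np.empty(p)
    chunk = max(1, int(max_chunk_bytes // max(n * p * 8, 1)))
    for start in range(0, p, chunk):
        cols = np.arange(start, min(start + chunk, p))
        big = np.repeat(X_val[None, :, :], cols.size, axis=0)
        for k, j in enumerate(cols):
            big[k, :, j] = X_val[rng.permutation(n), j]
        preds = model.predict(big.reshape(-1, p)).reshape(cols.size, n)
        imp[cols] = base - (preds == y_val[None, :]).mean(axis=1)
    return imp
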