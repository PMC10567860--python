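"""Independent reference implementations used as test oracles.

These are deliberately written in the most literal, textbook form, with no
code shared with the package, so that agreement with the package is
evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import itertools

import numpy as np


def nipals_pls1(X, y, n_components):
    """Textbook NIPALS PLS1 on a column-scaled X and raw y.

    Returns (fitted values in original y units, predict(X_new) closure).
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).ravel()
    y_mean = y.mean()
    yc = y - y_mean
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = X.T @ yc
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = t @ t
        pvec = X.T @ t / tt
        qa = yc @ t / tt
        X = X - np.outer(t, pvec)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
    B = W @ np.linalg.solve(P.T @ W, q)
    fitted = T @ q + y_mean

    def predict(X_new):
        return np.asarray(X_new, dtype=float) @ B + y_mean

    return fitted, predict


def krylov_pls1(X, y, n_components):
    """PLS1 fitted values via the Krylov-subspace characterization.

    The PLS1 coefficient after ``a`` components is the least-squares
    solution restricted to the Krylov space span{s, Gs, ..., G^{a-1}s}
    with s = X'y and G = X'X — a closed-form equivalence that shares no
    algorithmic structure with NIPALS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    y_mean = y.mean()
    yc = y - y_mean
    s = X.T @ yc
    G = X.T @ X
    K = np.empty((X.shape[1], n_components))
    v = s
    for a in range(n_components):
        K[:, a] = v
        v = G @ v
    # solve min ||yc - X K alpha||
    A = X @ K
    alpha, *_ = np.linalg.lstsq(A, yc, rcond=None)
    B = K @ alpha
    return X @ B + y_mean


def poisson_binomial_sf_enum(probs, k):
    """P(sum of independent Bernoulli(p_i) >= k) by exhaustive enumeration."""
    probs = list(map(float, probs))
    m = len(probs)
    if m > 15:
        raise ValueError("enumeration limited to 15 trials")
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=m):
        if sum(outcome) >= k:
            pr = 1.0
            for o, p in zip(outcome, probs):
                pr *= p if o else (1.0 - p)
            total += pr
    return total
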