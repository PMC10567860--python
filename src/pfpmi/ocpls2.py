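"""Orthogonally constrained PLS regression (oCPLS2) for PMI estimation.

The model regresses a response (the post-mortem interval, in hours) on an
autoscaled metabolite matrix while forcing every score component to be
orthogonal to external constraint factors (age, centered).  Each predictive
weight vector is chosen in the null space of ``Z.T @ X``, so the scores
``t = X w`` satisfy ``Z.T t = 0`` exactly and the latent space cannot
encode the confounder.  Optional non-predictive components remove
systematic X-variation that is orthogonal to both the response and the
constraint before the predictive regression (an OPLS-style filter).

Model selection uses repeated k-fold cross-validation maximizing Q2
(cross-validated R2); reliability is assessed with a randomization
(response-permutation) test; per-metabolite importance uses the VIP score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OCPLS2Model",
    "ModelPerformance",
    "fit",
    "predict",
    "performance_metrics",
    "repeated_cv",
    "select_components",
    "randomization_test",
    "vip",
]

_TOL = 1e-12
_ORTHO_TOL = 1e-8  # defining score-constraint orthogonality tolerance


@dataclass
class OCPLS2Model:
    """Fitted constrained latent-variable regression (scaled X space)."""

    x_weights: np.ndarray            # (p, A) unit-norm predictive weights
    x_loadings: np.ndarray           # (p, A)
    y_loadings: np.ndarray           # (A,)
    predictive_scores: np.ndarray    # (n, A)
    orth_weights: np.ndarray         # (p, A_o)
    orth_loadings: np.ndarray        # (p, A_o)
    non_predictive_scores: np.ndarray  # (n, A_o)
    coefficients: np.ndarray         # (p,) scaled X -> scaled y
    constraint: np.ndarray           # centered Z used at fit time (n, c)
    n_predictive: int
    n_non_predictive: int
    y_mean: float
    y_sd: float
    score_ss: np.ndarray = field(default=None)   # (A,) t't per component
    metabolite_names: list[str] | None = None


@dataclass
class ModelPerformance:
    """Calibration/validation summary in the units of the response (hours)."""

    r2: float
    q2: float
    sdec: float
    sdecv: float
    sdep: float | None = None
    p_r2: float | None = None
    p_q2: float | None = None
    n_predictive: int = 1
    n_non_predictive: int = 0


def _center_constraint(Z, n):
    if Z is None:
        return np.zeros((n, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return Z - Z.mean(axis=0)


def _null_project(v, M):
    """Project v onto the null space of M (rows = constraint factors)."""
    if M.shape[0] == 0:
        return v
    G = M @ M.T
    return v - M.T @ (np.linalg.pinv(G) @ (M @ v))


def _fit_core(X, y, Z, n_pred, n_orth):
    """NIPALS-style fit on preprocessed arrays; returns raw factor arrays.

    X: scaled predictors (copied), y: centered/scaled response (copied),
    Z: centered constraints.  Raises on rank deficiency.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    n, p = X.shape
    if Z.shape[1] >= p:
        raise ValueError("more constraint factors than predictors")

    Wo = np.zeros((p, n_orth))
    Po = np.zeros((p, n_orth))
    To = np.zeros((n, n_orth))
    for a in range(n_orth):
        M = Z.T @ X
        w = _null_project(X.T @ y, M)
        nw = np.linalg.norm(w)
        if nw < _TOL:
            raise ValueError("constrained weight vanished (rank/constraint conflict)")
        w /= nw
        t = X @ w
        tt = t @ t
        pl = X.T @ t / tt
        wo = pl - (w @ pl) * w
        wo = _null_project(wo, M)
        nwo = np.linalg.norm(wo)
        if nwo < _TOL:
            raise ValueError("no constraint-orthogonal non-predictive variation left")
        wo /= nwo
        to = X @ wo
        tto = to @ to
        if tto < _TOL:
            raise ValueError("degenerate non-predictive component")
        po = X.T @ to / tto
        X -= np.outer(to, po)
        Wo[:, a], Po[:, a], To[:, a] = wo, po, to

    W = np.zeros((p, n_pred))
    P = np.zeros((p, n_pred))
    T = np.zeros((n, n_pred))
    q = np.zeros(n_pred)
    tt_all = np.zeros(n_pred)
    for a in range(n_pred):
        M = Z.T @ X
        w = _null_project(X.T @ y, M)
        nw = np.linalg.norm(w)
        if nw < _TOL:
            raise ValueError("requested components exceed available rank")
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < _TOL:
            raise ValueError("requested components exceed available rank")
        pl = X.T @ t / tt
        qa = (y @ t) / tt
        X -= np.outer(t, pl)
        y = y - qa * t
        W[:, a], P[:, a], T[:, a], q[a], tt_all[a] = w, pl, t, qa, tt

    B = W @ np.linalg.solve(P.T @ W, q)
    return W, P, T, q, tt_all, Wo, Po, To, B


def fit(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    n_predictive: int = 1,
    n_non_predictive: int = 0,
    metabolite_names: list[str] | None = None,
) -> OCPLS2Model:
    """Fit the constrained model.

    ``X`` must already be column-scaled with the training statistics
    (see :func:`pfpmi.io_preprocess.autoscale`); ``y`` is the raw response
    in hours and is centered/scaled internally; ``Z`` holds raw constraint
    columns (age) and is centered internally.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    Zc = _center_constraint(Z, n)
    if Zc.shape[0] != n:
        raise ValueError("Z and y have different numbers of rows")
    y_mean = y.mean()
    y_sd = y.std(ddof=1)
    if y_sd <= 0:
        raise ValueError("constant response")
    ys = (y - y_mean) / y_sd

    W, P, T, q, tt, Wo, Po, To, B = _fit_core(X, ys, Zc, n_predictive, n_non_predictive)

    model = OCPLS2Model(
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        predictive_scores=T,
        orth_weights=Wo,
        orth_loadings=Po,
        non_predictive_scores=To,
        coefficients=B,
        constraint=Zc,
        n_predictive=n_predictive,
        n_non_predictive=n_non_predictive,
        y_mean=y_mean,
        y_sd=y_sd,
        score_ss=tt,
        metabolite_names=list(metabolite_names) if metabolite_names else None,
    )
    _check_constraint(model)
    return model


def _check_constraint(model: OCPLS2Model) -> None:
    """Always-on defining invariant: predictive scores orthogonal to Z."""
    Z = model.constraint
    if Z.shape[1] == 0:
        return
    T = model.predictive_scores
    tn = np.linalg.norm(T, axis=0)
    zn = np.linalg.norm(Z, axis=0)
    denom = np.outer(tn, np.where(zn > 0, zn, 1.0))
    rel = np.abs(T.T @ Z) / np.where(denom > 0, denom, 1.0)
    if rel.size and rel.max() > _ORTHO_TOL:
        raise RuntimeError(
            f"score-constraint orthogonality violated: {rel.max():.3e}"
        )


def _filter_orth(model: OCPLS2Model, X: np.ndarray) -> np.ndarray:
    for a in range(model.n_non_predictive):
        t = X @ model.orth_weights[:, a]
        X = X - np.outer(t, model.orth_loadings[:, a])
    return X


def predict(model: OCPLS2Model, X_new: np.ndarray) -> np.ndarray:
    """Predict the response (hours) for rows scaled with training statistics."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    p = model.coefficients.shape[0]
    if X_new.shape[1] != p:
        raise ValueError(
            f"panel mismatch: model expects {p} metabolites, got {X_new.shape[1]}"
        )
    Xf = _filter_orth(model, X_new.copy())
    return Xf @ model.coefficients * model.y_sd + model.y_mean


def fitted_values(model: OCPLS2Model, X_train: np.ndarray) -> np.ndarray:
    """Training-set fitted response in hours."""
    return predict(model, X_train)


def performance_metrics(y_true: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    """(error, R2) with error = sqrt(mean squared residual) — SDEC or SDEP.

    The root-mean-square convention uses the plain ``n`` denominator.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y_true) != len(y_hat) or len(y_true) < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    tss = np.sum((y_true - y_true.mean()) ** 2)
    if tss <= 0:
        raise ValueError("constant y_true: R2 undefined")
    rss = np.sum((y_true - y_hat) ** 2)
    return float(np.sqrt(rss / len(y_true))), float(1.0 - rss / tss)


def _cv_once(X, y, Z, n_pred, n_orth, folds):
    """One fold assignment; returns pooled PRESS or None if a fold is bad."""
    n = len(y)
    press = 0.0
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        y_tr = y[train]
        if y_tr.std() == 0:
            return None
        X_tr = X[train]
        mx = X_tr.mean(axis=0)
        sx = X_tr.std(axis=0, ddof=1)
        sx = np.where(sx > 0, sx, 1.0)
        Xs_tr = (X_tr - mx) / sx
        ym = y_tr.mean()
        ysd = y_tr.std(ddof=1)
        ys = (y_tr - ym) / ysd
        Zc = _center_constraint(Z[train] if Z is not None else None, train.sum())
        try:
            W, P, T, q, tt, Wo, Po, To, B = _fit_core(Xs_tr, ys, Zc, n_pred, n_orth)
        except ValueError:
            return None
        Xs_te = (X[test_idx] - mx) / sx
        for a in range(n_orth):
            t = Xs_te @ Wo[:, a]
            Xs_te = Xs_te - np.outer(t, Po[:, a])
        y_hat = Xs_te @ B * ysd + ym
        press += np.sum((y[test_idx] - y_hat) ** 2)
    return press


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    n_predictive: int = 1,
    n_non_predictive: int = 0,
    k: int = 5,
    repetitions: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Repeated k-fold cross-validation; returns (Q2, SDECV).

    For each repetition a fresh random fold assignment is drawn; scaling
    statistics and the model are recomputed inside every training fold and
    applied to the held-out fold.  Q2 = 1 - PRESS/TSS is computed per
    repetition from the pooled held-out residuals and averaged; SDECV is
    the mean over repetitions of sqrt(PRESS/n).  Repetitions in which a
    training fold loses all response variance are discarded with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    tss = np.sum((y - y.mean()) ** 2)
    q2s, sdecvs = [], []
    for _ in range(repetitions):
        folds = np.array_split(rng.permutation(n), k)
        press = _cv_once(X, y, Z, n_predictive, n_non_predictive, folds)
        if press is None:
            warnings.warn("repetition discarded: degenerate training fold")
            continue
        q2s.append(1.0 - press / tss)
        sdecvs.append(np.sqrt(press / n))
    if not q2s:
        raise ValueError("all cross-validation repetitions were discarded")
    return float(np.mean(q2s)), float(np.mean(sdecvs))


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    max_predictive: int = 3,
    max_non_predictive: int = 2,
    k: int = 5,
    repetitions: int = 20,
    seed: int | None = None,
) -> tuple[int, int]:
    """Pick (n_predictive, n_non_predictive) maximizing mean Q2.

    All configurations are scored on the same fold sequences (paired
    comparison); ties break toward fewer components because only a strict
    Q2 improvement replaces the incumbent.
    """
    if max_predictive < 1:
        raise ValueError("max_predictive must be >= 1")
    best = (1, 0)
    best_q2 = -np.inf
    configs = sorted(
        ((a, o) for a in range(1, max_predictive + 1)
         for o in range(0, max_non_predictive + 1)),
        key=lambda c: (c[0] + c[1], c[1]),
    )
    for a, o in configs:
        try:
            q2, _ = repeated_cv(
                X, y, Z, a, o, k=k, repetitions=repetitions,
                rng=np.random.default_rng(seed),
            )
        except ValueError:
            continue
        if q2 > best_q2:
            best_q2, best = q2, (a, o)
    return best


def randomization_test(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    n_predictive: int = 1,
    n_non_predictive: int = 0,
    n_permutations: int = 999,
    k: int = 5,
    repetitions: int = 20,
    seed: int | None = None,
) -> tuple[float, float]:
    """Response-permutation test of R2 and Q2; returns (p_r2, p_q2).

    ``y`` is permuted while X and Z stay aligned with each other; the full
    pipeline (fit at the fixed component configuration plus repeated CV) is
    re-run per permutation.  p = (1 + #{permuted >= observed}) / (1 + N).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_perm, ss_cv = root.spawn(2)
    rng_perm = np.random.default_rng(ss_perm)

    def _stats(y_cur, cv_seed_seq):
        model = fit(X, y_cur, Z, n_predictive, n_non_predictive)
        _, r2 = performance_metrics(y_cur, predict(model, X))
        q2, _ = repeated_cv(
            X, y_cur, Z, n_predictive, n_non_predictive,
            k=k, repetitions=repetitions,
            rng=np.random.default_rng(cv_seed_seq),
        )
        return r2, q2

    obs_r2, obs_q2 = _stats(y, ss_cv)
    ge_r2 = ge_q2 = 0
    for i in range(n_permutations):
        y_perm = rng_perm.permutation(y)
        r2_p, q2_p = _stats(y_perm, root.spawn(1)[0])
        ge_r2 += r2_p >= obs_r2
        ge_q2 += q2_p >= obs_q2
    p_r2 = (1 + ge_r2) / (1 + n_permutations)
    p_q2 = (1 + ge_q2) / (1 + n_permutations)
    return float(p_r2), float(p_q2)


def vip(model: OCPLS2Model) -> np.ndarray:
    """Variable Influence on Projection scores (predictive components only).

    VIP_j = sqrt( p * sum_a SSY_a (w_aj/|w_a|)^2 / sum_a SSY_a ), where
    SSY_a is the response variance explained by component a.  Squared VIPs
    average to 1 across predictors.
    """
    if model.n_predictive < 1:
        raise ValueError("model has no predictive component")
    W = model.x_weights
    p = W.shape[0]
    ssy = model.y_loadings**2 * model.score_ss   # q_a^2 * t_a't_a
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wn2 @ ssy) / ssy.sum())
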