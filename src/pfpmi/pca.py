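"""Exploratory PCA with Hotelling T2 and Q-residual outlier diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import norm

from .io_preprocess import ScaledTable

__all__ = ["PCAModel", "fit_pca", "choose_n_components", "outlier_tests"]


@dataclass
class PCAModel:
    """PCA of an autoscaled table.

    ``loadings`` has orthonormal columns (one per component); ``scores`` is
    the projection of the scaled data onto them.  ``eigenvalues`` holds the
    full spectrum of the covariance matrix (all ranks), needed by the
    Q-residual limit; ``explained_variance`` is its leading slice.
    """

    loadings: np.ndarray            # (p, k)
    scores: np.ndarray              # (n, k)
    explained_variance: np.ndarray  # (k,)
    eigenvalues: np.ndarray         # full spectrum, length min(n-1, p)
    n_components: int
    scaled_values: np.ndarray = field(repr=False, default=None)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.eigenvalues.sum()


def fit_pca(scaled: ScaledTable | np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA by SVD of the (already centered/scaled) data matrix.

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so scores are invariant to row order.
    """
    X = scaled.values if isinstance(scaled, ScaledTable) else np.asarray(scaled, float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for a {n}x{p} table"
        )
    U, s, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    loadings = Vt[:n_components].T
    # deterministic sign convention
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_components)])
    loadings = loadings * flip
    scores = X @ loadings
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance=eigenvalues[:n_components],
        eigenvalues=eigenvalues[:max_rank],
        n_components=n_components,
        scaled_values=X,
    )


def choose_n_components(
    scaled: ScaledTable | np.ndarray, threshold: float = 0.8, cap: int = 5
) -> int:
    """Smallest k reaching ``threshold`` cumulative explained variance, capped."""
    X = scaled.values if isinstance(scaled, ScaledTable) else np.asarray(scaled, float)
    n, p = X.shape
    s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    ev = s**2
    ratio = np.cumsum(ev) / ev.sum()
    k = int(np.searchsorted(ratio, threshold) + 1)
    return min(k, cap, min(n - 1, p))


def outlier_tests(model: PCAModel, alpha: float = 0.05) -> pd.DataFrame:
    """Per-sample Hotelling T2 and Q-residual outlier flags.

    The T2 limit uses the F-distribution scaling of Hotelling's statistic;
    the Q (squared residual distance) limit uses the Jackson-Mudholkar
    normal approximation built from the residual eigenvalue spectrum.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    X = model.scaled_values
    if X is None:
        raise ValueError("model carries no data; fit with fit_pca")
    n, k = model.scores.shape

    t2 = np.sum(model.scores**2 / model.explained_variance, axis=1)
    t2_limit = (
        k * (n - 1) * (n + 1) / (n * (n - k)) * f_dist.ppf(1 - alpha, k, n - k)
    )
    out = pd.DataFrame(
        {
            "t2": t2,
            "t2_flag": t2 > t2_limit,
        }
    )
    out.attrs["t2_limit"] = float(t2_limit)

    resid = X - X.mean(axis=0) - model.scores @ model.loadings.T
    q = np.sum(resid**2, axis=1)
    resid_eig = model.eigenvalues[k:]
    theta1 = resid_eig.sum()
    if theta1 <= 1e-12 * model.eigenvalues.sum():
        warnings.warn("zero residual variance: Q test skipped")
        out["q"] = q
        out["q_flag"] = False
        out.attrs["q_limit"] = np.nan
        return out
    theta2 = np.sum(resid_eig**2)
    theta3 = np.sum(resid_eig**3)
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    if h0 < 0.001:
        h0 = 0.001
    c_alpha = norm.ppf(1 - alpha)
    q_limit = theta1 * (
        c_alpha * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    ) ** (1.0 / h0)
    out["q"] = q
    out["q_flag"] = q > q_limit
    out.attrs["q_limit"] = float(q_limit)
    return out
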