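"""VIP-guided stability selection over Binary-Matrix-Sampling subsamples.

Relevant metabolites are discovered by repeating a cross-validated subset
search on random subsamples of the data: each subsample keeps rows
(samples) and columns (metabolites) independently with probability 0.7
(Binary Matrix Sampling); within each subsample, VIP-guided backward
elimination finds the predictor subset giving the best Q2; a metabolite's
selection count over subsamples is then compared with the count expected
under size-matched random choice, using the exact Poisson-binomial null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ocpls2

__all__ = [
    "StabilitySettings",
    "bms_subsamples",
    "best_subset",
    "poisson_binomial_pmf",
    "poisson_binomial_sf",
    "relevance_test",
    "run_stability_selection",
]


@dataclass
class StabilitySettings:
    """Tunable parameters of the stability-selection procedure."""

    n_subsamples: int = 200
    probability: float = 0.7
    alpha: float = 0.05
    min_rows: int = 8
    min_cols: int = 2
    cv_k: int = 5
    cv_repetitions: int = 5   # cheaper CV inside subsamples than the outer model
    n_predictive: int = 1
    n_non_predictive: int = 0
    vip_threshold: float = 1.0


def bms_subsamples(
    n_samples: int,
    n_predictors: int,
    probability: float = 0.7,
    count: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_rows: int = 8,
    min_cols: int = 2,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw Bernoulli row/column masks; undersized masks are redrawn."""
    if not 0 < probability < 1:
        raise ValueError("probability must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    min_rows = min(min_rows, n_samples)
    min_cols = min(min_cols, n_predictors)
    masks = []
    n_redrawn = 0
    while len(masks) < count:
        rows = rng.random(n_samples) < probability
        cols = rng.random(n_predictors) < probability
        if rows.sum() < min_rows or cols.sum() < min_cols:
            n_redrawn += 1
            continue
        masks.append((rows, cols))
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} undersized subsample mask(s)")
    return masks


def _subset_q2(X, y, Z, cols, settings, rng):
    q2, _ = ocpls2.repeated_cv(
        X[:, cols],
        y,
        Z,
        settings.n_predictive,
        settings.n_non_predictive,
        k=settings.cv_k,
        repetitions=settings.cv_repetitions,
        rng=rng,
    )
    return q2


def best_subset(
    X_sub: np.ndarray,
    y_sub: np.ndarray,
    Z_sub: np.ndarray | None,
    settings: StabilitySettings | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Best-performing predictor subset by VIP-guided backward elimination.

    Starting from all columns of the subsample: fit the constrained model
    on the full rows, drop every predictor with VIP below the threshold,
    re-evaluate Q2; stop when Q2 no longer improves, no predictor is
    dropped, or fewer than 2 predictors would remain.  Returns the integer
    indices (into ``X_sub`` columns) of the subset with maximal Q2 along
    the elimination path.  ``X_sub`` holds raw concentrations; scaling is
    redone inside every cross-validation fold.
    """
    settings = settings or StabilitySettings()
    if rng is None:
        rng = np.random.default_rng()
    n, p = X_sub.shape
    cols = np.arange(p)
    path = []
    prev_q2 = -np.inf
    while True:
        q2 = _subset_q2(X_sub, y_sub, Z_sub, cols, settings, rng)
        path.append((q2, cols.copy()))
        if q2 <= prev_q2 or len(cols) < 2:
            break
        prev_q2 = q2
        # full-data fit on the current subset to rank predictors by VIP
        mx = X_sub[:, cols].mean(axis=0)
        sx = X_sub[:, cols].std(axis=0, ddof=1)
        sx = np.where(sx > 0, sx, 1.0)
        Xs = (X_sub[:, cols] - mx) / sx
        try:
            model = ocpls2.fit(
                Xs, y_sub, Z_sub, settings.n_predictive, settings.n_non_predictive
            )
        except ValueError:
            break
        keep = ocpls2.vip(model) >= settings.vip_threshold
        if keep.all() or keep.sum() < 2:
            break
        cols = cols[keep]
    best_q2, best_cols = max(path, key=lambda e: e[0])
    return best_cols


def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact PMF of a sum of independent Bernoulli(p_i) via DP convolution."""
    pmf = np.array([1.0])
    for p in np.asarray(probs, dtype=float):
        nxt = np.zeros(len(pmf) + 1)
        nxt[:-1] += pmf * (1.0 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def poisson_binomial_sf(probs: np.ndarray, k: int) -> float:
    """P(count >= k) for the Poisson-binomial distribution."""
    pmf = poisson_binomial_pmf(probs)
    k = max(int(k), 0)
    return float(pmf[k:].sum()) if k < len(pmf) else 0.0


def relevance_test(
    selection_counts: np.ndarray,
    availability: np.ndarray,
    subset_sizes: np.ndarray,
    n_available: np.ndarray,
    alpha: float = 0.05,
    metabolite_names: list[str] | None = None,
) -> pd.DataFrame:
    """Compare observed selection counts with the random-choice null.

    For metabolite j and subsample s in which it was available, the null
    selection probability is (subset size chosen in s) / (number of
    predictors available in s); the null count distribution is the exact
    Poisson-binomial over those subsamples.  One-sided
    p = P(count >= observed); relevant iff p < alpha.
    """
    availability = np.asarray(availability, dtype=bool)
    n_sub, p = availability.shape
    if n_sub < 50:
        raise ValueError("need counts from at least 50 subsamples")
    subset_sizes = np.asarray(subset_sizes, dtype=float)
    n_available = np.asarray(n_available, dtype=float)
    null_prob_s = subset_sizes / n_available   # per-subsample inclusion prob
    rows = []
    for j in range(p):
        avail = availability[:, j]
        probs = null_prob_s[avail]
        obs = int(selection_counts[j])
        pval = poisson_binomial_sf(probs, obs)
        rows.append(
            {
                "metabolite": metabolite_names[j] if metabolite_names else f"x{j}",
                "selection_count": obs,
                "n_available": int(avail.sum()),
                "selection_frequency": obs / max(int(avail.sum()), 1),
                "null_frequency": float(probs.mean()) if probs.size else 0.0,
                "p_value": pval,
                "relevant": pval < alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["n_subsamples"] = n_sub
    return out


def run_stability_selection(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    settings: StabilitySettings | None = None,
    seed: int | None = None,
    metabolite_names: list[str] | None = None,
) -> pd.DataFrame:
    """Full procedure: BMS subsamples -> best subsets -> relevance report.

    ``X`` holds raw concentrations (scaling is redone inside each
    subsample's cross-validation folds); ``y`` the response in hours;
    ``Z`` the constraint columns.
    """
    settings = settings or StabilitySettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_masks, ss_cv = root.spawn(2)
    masks = bms_subsamples(
        n, p,
        probability=settings.probability,
        count=settings.n_subsamples,
        rng=np.random.default_rng(ss_masks),
        min_rows=settings.min_rows,
        min_cols=settings.min_cols,
    )
    rng_cv = np.random.default_rng(ss_cv)

    counts = np.zeros(p, dtype=int)
    availability = np.zeros((len(masks), p), dtype=bool)
    subset_sizes = np.zeros(len(masks))
    n_available = np.zeros(len(masks))
    kept = 0
    for rows, cols in masks:
        col_idx = np.flatnonzero(cols)
        try:
            sel = best_subset(
                X[np.ix_(rows, col_idx)],
                y[rows],
                Z[rows] if Z is not None else None,
                settings,
                rng_cv,
            )
        except ValueError:
            warnings.warn("subsample skipped: model could not be fitted")
            continue
        chosen = col_idx[sel]
        counts[chosen] += 1
        availability[kept, col_idx] = True
        subset_sizes[kept] = len(chosen)
        n_available[kept] = len(col_idx)
        kept += 1
    if kept < 50:
        raise ValueError("fewer than 50 usable subsamples")
    return relevance_test(
        counts,
        availability[:kept],
        subset_sizes[:kept],
        n_available[:kept],
        alpha=settings.alpha,
        metabolite_names=metabolite_names,
    )
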