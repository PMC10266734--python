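"""Dominance analysis: apportioning a regression's fit across predictors.

Total (general) dominance averages, for each predictor, the increase in
R^2 from adding it to a submodel — first within each submodel size
(including the empty model), then across sizes. This Shapley-value
weighting makes the per-predictor dominances sum exactly to the full
model's R^2, so a percentage of relative importance can be read off
directly. A flat average over all submodels is also available; it matches
a common informal description of the procedure but does not satisfy the
exact sum property.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["DominanceResult", "all_subsets_fit", "total_dominance", "dominance_analysis"]

MAX_PREDICTORS = 15


@dataclass
class DominanceResult:
    predictor_names: list[str]
    total_dominance: np.ndarray      # per predictor, sums to full-model R^2
    percent_importance: np.ndarray   # per predictor, sums to 100
    full_model_r2: float
    full_model_adj_r2: float
    subset_fits: dict[frozenset, float]      # R^2 per non-empty predictor subset
    subset_adj_fits: dict[frozenset, float]  # adjusted R^2 alongside


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    n = y.size
    D = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("target has zero variance")
    return 1.0 - np.sum(resid**2) / tss


def all_subsets_fit(X: np.ndarray, y: np.ndarray,
                    ) -> tuple[dict[frozenset, float], dict[frozenset, float]]:
    """OLS R^2 (and adjusted R^2) for every non-empty predictor subset.

    2^p - 1 submodels; p is capped at 15 to guard against explosion.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p > MAX_PREDICTORS:
        raise ValueError(f"too many predictors ({p} > {MAX_PREDICTORS})")
    if n <= p + 1:
        raise ValueError("need more observations than predictors plus intercept")
    fits: dict[frozenset, float] = {}
    adj: dict[frozenset, float] = {}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            r2 = _ols_r2(X[:, subset], y)
            fits[frozenset(subset)] = r2
            adj[frozenset(subset)] = 1.0 - (1.0 - r2) * (n - 1) / (n - size - 1)
    return fits, adj


def total_dominance(subset_fits: dict[frozenset, float], p: int,
                    flat_average: bool = False) -> np.ndarray:
    """Total dominance per predictor from a complete subset-fit mapping.

    Default weighting averages the incremental R^2 of predictor j over the
    subsets not containing j within each subset size (the empty model
    counts as size 0 with R^2 = 0), then across the p sizes; the results
    sum exactly to the full-model R^2. ``flat_average`` instead averages
    the increments over all submodels uniformly.
    """
    expected = 2**p - 1
    if len(subset_fits) != expected:
        raise ValueError(f"incomplete subset mapping: {len(subset_fits)} != {expected}")
    full = frozenset(range(p))
    dom = np.zeros(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        if flat_average:
            incs = [subset_fits[frozenset(S) | {j}] - (subset_fits[frozenset(S)] if S else 0.0)
                    for size in range(0, p) for S in combinations(others, size)]
            dom[j] = float(np.mean(incs))
        else:
            per_size = []
            for size in range(0, p):
                incs = [subset_fits[frozenset(S) | {j}] - (subset_fits[frozenset(S)] if S else 0.0)
                        for S in combinations(others, size)]
                per_size.append(np.mean(incs))
            dom[j] = float(np.mean(per_size))
    return dom


def dominance_analysis(X: np.ndarray, y: np.ndarray,
                       predictor_names: list[str] | None = None,
                       flat_average: bool = False) -> DominanceResult:
    """Run the full dominance analysis of y on the columns of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]
    fits, adj = all_subsets_fit(X, y)
    dom = total_dominance(fits, p, flat_average=flat_average)
    full = fits[frozenset(range(p))]
    if full <= 0:
        raise ValueError("full model explains no variance; importances undefined")
    return DominanceResult(
        predictor_names=list(predictor_names),
        total_dominance=dom,
        percent_importance=dom / dom.sum() * 100.0,
        full_model_r2=full,
        full_model_adj_r2=adj[frozenset(range(p))],
        subset_fits=fits,
        subset_adj_fits=adj,
    )
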