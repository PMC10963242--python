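"""Feature selection: pairwise-correlation fitness (CFS) and ReliefF.

Two selectors, one per family the BP-estimation literature uses:

* **CFS** scores a candidate feature subset by the Pearson correlation
  between pairwise response differences ``Ey = y_i - y_j`` and signed
  pairwise feature-space distances
  ``EX = sign(Ey) * sqrt(mean_k (X_ik - X_jk)^2)`` over all instance
  pairs; a subset whose geometry orders instances the way the response
  does scores near 1.  Selection is greedy forward search maximizing the
  fitness.

* **ReliefF** weights each feature by how well it separates each sampled
  instance from its nearest *miss* (different response) relative to its
  nearest *hit* (similar response), accumulating
  ``W_i += (diff_i(R, M) - diff_i(R, H)) / m`` over ``m`` sampled
  instances.  Blood pressure is continuous, so "same response" is defined
  by quantiles of the response-difference distribution (hits below the
  10th percentile, misses above the 90th); a regression-style mode that
  weights by the response difference itself is available behind a flag.

Features are standardized (CFS) or scaled to [0, 1] (ReliefF) before any
distance is computed: the 48 PPG features mix seconds, ratios and
spectral magnitudes, and unscaled distances would be dominated by a
single unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SelectionResult",
    "DEFAULT_SUBSET_SIZES",
    "cfs_fitness",
    "cfs_select",
    "relieff_weights",
    "relieff_select",
]

#: Published subset sizes per target and method (overridable everywhere).
DEFAULT_SUBSET_SIZES = {
    "cfs": {"sbp": 15, "map": 16, "dbp": 16},
    "relieff": {"sbp": 15, "map": 16, "dbp": 15},
}


@dataclass
class SelectionResult:
    """Ranked features and the selected subset for one target/method."""

    target: str
    method: str
    ranked_features: list[str]
    scores: list[float]
    selected: list[str]

    @property
    def subset_size(self) -> int:
        return len(self.selected)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked_features) + 1),
                "feature_name": self.ranked_features,
                "score": self.scores,
                "selected": [f in set(self.selected) for f in self.ranked_features],
            }
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[1])]


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def cfs_fitness(X, y) -> float:
    """Correlation fitness of a feature subset.

    ``X`` is the instance-by-feature matrix restricted to the candidate
    subset; features are standardized internally before the distance.
    Returns the Pearson correlation between the signed per-pair feature
    distances and the per-pair response differences over all unordered
    instance pairs; if either side has zero variance the fitness is
    defined as 0 (with a warning).
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_instances, n_features) aligned with y")
    m, p = X.shape
    if m < 3:
        raise ValueError("need at least 3 instances")
    if p == 0:
        raise ValueError("subset must be nonempty")

    Z = _standardize(X)
    # pdist enumerates pairs (i, j) with i < j, matching Ey = y_i - y_j
    dist = pdist(Z, metric="euclidean") / np.sqrt(p)
    Ey = y[:, None] - y[None, :]
    Ey = Ey[np.triu_indices(m, k=1)]
    EX = np.where(Ey >= 0, dist, -dist)
    if EX.std() == 0 or Ey.std() == 0:
        warnings.warn("zero variance in pairwise distances; fitness defined as 0")
        return 0.0
    return float(np.corrcoef(EX, Ey)[0, 1])


def cfs_select(
    X,
    y,
    target_size: int | None = None,
    tol: float = 1e-4,
    target: str = "",
) -> SelectionResult:
    """Greedy forward selection maximizing the correlation fitness.

    Starting from the empty set, repeatedly adds the feature whose
    inclusion most increases the subset fitness; stops when no addition
    improves it by more than ``tol``, or when ``target_size`` features
    have been selected if a size is given.  Ties break toward the lower
    feature index (canonical table order).
    """
    X, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n_feat = X.shape[1]
    if target_size is not None and not 1 <= target_size <= n_feat:
        raise ValueError(f"target_size must lie in [1, {n_feat}]")

    selected: list[int] = []
    scores: list[float] = []
    current = -np.inf
    remaining = list(range(n_feat))
    limit = target_size if target_size is not None else n_feat
    while remaining and len(selected) < limit:
        best_gain, best_j, best_score = -np.inf, None, None
        for j in remaining:
            score = cfs_fitness(X[:, selected + [j]], y)
            gain = score - (current if np.isfinite(current) else 0.0)
            if gain > best_gain + 1e-15:
                best_gain, best_j, best_score = gain, j, score
        if best_j is None:
            break
        if target_size is None and best_gain <= tol:
            break
        selected.append(best_j)
        scores.append(float(best_score))
        remaining.remove(best_j)
        current = best_score
    return SelectionResult(
        target=target,
        method="cfs",
        ranked_features=[names[j] for j in selected],
        scores=scores,
        selected=[names[j] for j in selected],
    )


def _scale01(X: np.ndarray) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = hi - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng


def relieff_weights(
    X,
    y,
    m: int | None = None,
    k_neighbors: int = 1,
    diff_mode: str = "continuous",
    hit_quantile: float = 0.10,
    miss_quantile: float = 0.90,
    mode: str = "quantile",
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """ReliefF feature weights for a continuous response.

    For each of ``m`` randomly sampled target instances ``R`` the nearest
    ``k_neighbors`` hits ``H`` (instances whose response difference from
    ``R`` is below the ``hit_quantile`` of all response differences) and
    misses ``M`` (above the ``miss_quantile``) are found by Euclidean
    distance over all [0, 1]-scaled features, and every feature weight is
    updated by ``(diff(R, M) - diff(R, H)) / m`` (averaged over the k
    neighbors).  ``diff_mode="continuous"`` uses the range-normalized
    absolute difference; ``"binary"`` scores 0/1 on (in)equality to 1e-9.
    ``mode="rrelieff"`` switches to a regression-style update in which
    each neighbor's contribution is signed and weighted by its response
    difference instead of being classed hit/miss.

    Weights are returned in feature order; with constant features the
    diffs are identically zero, so their weights are exactly 0.
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 instances")
    if m is None:
        m = n
    if not 1 <= m <= n:
        raise ValueError(f"m must lie in [1, {n}]")
    if not 1 <= k_neighbors < n:
        raise ValueError(f"k_neighbors must lie in [1, {n - 1}]")
    if diff_mode not in ("continuous", "binary"):
        raise ValueError("diff_mode must be 'continuous' or 'binary'")
    if mode not in ("quantile", "rrelieff"):
        raise ValueError("mode must be 'quantile' or 'rrelieff'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Z = _scale01(X)
    dist = squareform(pdist(Z, metric="euclidean"))
    np.fill_diagonal(dist, np.inf)

    def diffs(i: int, j: np.ndarray) -> np.ndarray:
        d = np.abs(Z[i] - Z[j])  # ranges are 1 after scaling
        if diff_mode == "binary":
            return (d > 1e-9).astype(float)
        return d

    weights = np.zeros(p)
    targets = rng.choice(n, size=m, replace=False)
    if mode == "rrelieff":
        dy_all = np.abs(y[:, None] - y[None, :])
        norm = dy_all.max() or 1.0
        for i in targets:
            order = np.argsort(dist[i])[:k_neighbors]
            for j in order:
                sign = 2.0 * (dy_all[i, j] / norm) - 1.0
                weights += sign * diffs(i, np.array([j]))[0] / m
        return weights

    for i in targets:
        dy = np.abs(y - y[i])
        dy[i] = np.nan
        lo = np.nanquantile(dy, hit_quantile)
        hi = np.nanquantile(dy, miss_quantile)
        hits = np.flatnonzero(dy <= lo)
        misses = np.flatnonzero(dy >= hi)
        if hits.size == 0 or misses.size == 0:
            continue
        h = hits[np.argsort(dist[i, hits])[:k_neighbors]]
        ms = misses[np.argsort(dist[i, misses])[:k_neighbors]]
        weights -= diffs(i, h).mean(axis=0) / m
        weights += diffs(i, ms).mean(axis=0) / m
    return weights


def relieff_select(
    weights: np.ndarray,
    target_size: int,
    feature_names: list[str] | None = None,
    target: str = "",
) -> SelectionResult:
    """Top ``target_size`` features by ReliefF weight (ties: lower index)."""
    weights = np.asarray(weights, dtype=float)
    if not 1 <= target_size <= weights.size:
        raise ValueError(f"target_size must lie in [1, {weights.size}]")
    names = feature_names or [str(i) for i in range(weights.size)]
    # stable sort on -weight keeps lower indices first among ties
    order = np.argsort(-weights, kind="stable")
    ranked = [names[j] for j in order]
    scores = [float(weights[j]) for j in order]
    return SelectionResult(
        target=target,
        method="relieff",
        ranked_features=ranked,
        scores=scores,
        selected=ranked[:target_size],
    )
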