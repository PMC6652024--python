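"""Clustering primitives behind the sparse-cluster flagger.

Three pieces make up the detector's computational core:

* a sampling-based approximation of the number of clusters *k*, selected by
  Bayesian information criterion over one-dimensional Gaussian-mixture fits
  on small seeded subsamples (cheap enough to run once per fold);
* hybrid hierarchical--K-means ("HK-means"): a Ward-linkage agglomerative
  cut supplies the initial centroids, removing K-means' dependence on random
  initialisation, then Lloyd iterations refine the partition until the
  assignments stop changing;
* the flag rule: after a census of cluster populations p_1..p_k, every point
  in a cluster whose population is at most floor(alpha * fold_length) is
  flagged as implausible.  With the coupled setting alpha = 1/n this flags
  only singleton clusters.

Everything operates on one-dimensional value vectors; observation types are
always clustered separately.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ClusterModel",
    "approximate_k",
    "hierarchical_centroids",
    "kmeans_refine",
    "hkmeans",
    "cluster_census",
    "flag_threshold",
    "flag_sparse",
]

# Floor on mixture-component variance relative to data variance; prevents
# the likelihood diverging when a component collapses onto a single point
# while still letting genuinely tight components win.
_VAR_FLOOR = 1e-6
# EM only has to rank candidate k by BIC, not polish the likelihood, so a
# modest iteration cap and relative tolerance suffice.
_EM_MAX_ITER = 30
_EM_TOL = 1e-6
# stop widening the BIC search after this many consecutive non-improvements
_BIC_PATIENCE = 2


@dataclass
class ClusterModel:
    """A fitted 1-D partition: centroids, assignments and populations.

    ``distortion`` is the within-cluster sum of squares
    sum_i (x(i) - mu(C(i)))^2; ``distortion_history`` records it after each
    Lloyd assignment step (non-increasing by construction).
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    populations: np.ndarray
    distortion: float
    distortion_history: list = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        self.populations = np.asarray(self.populations, dtype=int)
        if self.k != self.centroids.size or self.k != self.populations.size:
            raise ValueError("inconsistent k / centroids / populations")
        if self.populations.sum() != self.assignments.size:
            raise ValueError("populations must sum to the number of points")
        if self.populations.size and self.populations.min() < 1:
            raise ValueError("empty clusters must be dropped, not kept")

    @property
    def n_points(self) -> int:
        return int(self.assignments.size)


# ---------------------------------------------------------------------------
# cluster-number approximation
# ---------------------------------------------------------------------------

def _gmm_loglik_1d(x: np.ndarray, k: int, groups: np.ndarray | None = None) -> float:
    """Maximised log-likelihood of a k-component 1-D Gaussian mixture.

    Deterministic EM.  When ``groups`` (a hard partition into k groups) is
    given, components are initialised from the group means, variances and
    proportions — a gap-aware start that lets components latch onto far
    tail points; otherwise means start at the (i/(k+1))-quantiles with a
    common variance.  Variances are floored at _VAR_FLOOR times the data
    variance.
    """
    n = x.size
    var0 = max(float(x.var()), 1e-12)
    floor = _VAR_FLOOR * var0
    if groups is None:
        means = np.quantile(x, (np.arange(k) + 1.0) / (k + 1.0))
        var = np.full(k, var0)
        logw = np.full(k, -math.log(k))
    else:
        labels = np.unique(groups)
        means = np.array([x[groups == g].mean() for g in labels])
        var = np.array(
            [max(float(x[groups == g].var()), floor) for g in labels]
        )
        logw = np.log(
            np.array([np.sum(groups == g) for g in labels]) / n
        )
        k = labels.size
    xi = x[:, None]
    ll_old = -np.inf
    for _ in range(_EM_MAX_ITER):
        logp = (
            logw
            - 0.5 * (np.log(2.0 * np.pi * var) + (xi - means) ** 2 / var)
        )
        m = logp.max(axis=1)
        lse = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        logw = np.log(nk / n)
        means = (resp * xi).sum(axis=0) / nk
        var = (resp * (xi - means) ** 2).sum(axis=0) / nk
        var = np.maximum(var, floor)
        if ll - ll_old <= _EM_TOL * (abs(ll) + 1.0):
            break
        ll_old = ll
    return ll


def _bic_select_k(x: np.ndarray, k_max: int) -> int:
    """k in 1..k_max minimising BIC = -2 loglik + (3k - 1) log n.

    Mixture fits at k >= 2 are initialised from the Ward-cut partition at k
    (the tree is built once and cut repeatedly).  The search stops early
    once BIC has failed to improve for _BIC_PATIENCE consecutive k.
    """
    n = x.size
    n_distinct = np.unique(x).size
    k_hi = min(k_max, n_distinct)
    tree = linkage(x[:, None], method="ward") if k_hi >= 2 else None
    best_k, best_bic = 1, np.inf
    stale = 0
    for k in range(1, k_hi + 1):
        groups = (
            fcluster(tree, t=k, criterion="maxclust") if k >= 2 else None
        )
        ll = _gmm_loglik_1d(x, k, groups=groups)
        bic = -2.0 * ll + (3 * k - 1) * math.log(n)
        if bic < best_bic:
            best_k, best_bic = k, bic
            stale = 0
        else:
            stale += 1
            if stale >= _BIC_PATIENCE:
                break
    return best_k


def approximate_k(
    values,
    k_max: int = 10,
    seed: int = 0,
    *,
    n_subsamples: int = 10,
    subsample_size: int = 500,
) -> int:
    """Approximate the number of clusters in a 1-D value vector.

    Draws ``n_subsamples`` seeded subsamples of ``subsample_size`` points
    (without replacement; a single estimate on the full vector when it is no
    larger than a subsample), selects k on each by BIC over Gaussian-mixture
    fits, and returns the rounded mean of the per-subsample estimates.
    Values are standardised internally, so the estimate is invariant under
    affine transforms of the input.

    Returns k in 1..min(k_max, #distinct values); 1 for a constant vector.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        return 1
    n_distinct = np.unique(x).size
    if n_distinct == 1:
        return 1
    sd = x.std(ddof=1)
    z = (x - x.mean()) / sd
    if x.size <= subsample_size:
        samples = [z]
    else:
        rng = np.random.default_rng(seed)
        samples = [
            rng.choice(z, size=subsample_size, replace=False)
            for _ in range(n_subsamples)
        ]
    ks = [_bic_select_k(s, k_max) for s in samples]
    k = int(math.floor(float(np.mean(ks)) + 0.5))
    return max(1, min(k, k_max, n_distinct))


# ---------------------------------------------------------------------------
# HK-means
# ---------------------------------------------------------------------------

def hierarchical_centroids(
    values,
    k: int,
    *,
    max_points: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Initial centroids from an agglomerative (Ward, Euclidean) cut at k.

    The dendrogram is cut into k groups and each group's mean becomes a
    centroid (returned in ascending order).  For inputs larger than
    ``max_points`` the linkage is computed on a seeded subsample of that
    size; the subsequent Lloyd refinement assigns the remaining points.  If
    k exceeds the number of distinct values it is reduced with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    n_distinct = np.unique(x).size
    if k > n_distinct:
        warnings.warn(
            f"requested k={k} exceeds {n_distinct} distinct values; reducing",
            stacklevel=2,
        )
        k = n_distinct
    if k <= 1:
        return np.array([x.mean()])
    if x.size > max_points:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_points, replace=False)
        # the subsample can lose distinct values
        k = min(k, np.unique(x).size)
        if k <= 1:
            return np.array([x.mean()])
    z = linkage(x[:, None], method="ward")
    groups = fcluster(z, t=k, criterion="maxclust")
    cents = np.array([x[groups == g].mean() for g in np.unique(groups)])
    return np.sort(cents)


def kmeans_refine(values, initial_centroids, max_iter: int = 100) -> ClusterModel:
    """Lloyd iterations from given centroids until assignments are stable.

    Ties in the assignment step go to the lowest cluster index; clusters
    that lose all their points are dropped (k reduced) rather than
    re-seeded.  The within-cluster sum of squares is recorded after every
    assignment step and is non-increasing.
    """
    x = np.asarray(values, dtype=float).ravel()
    c = np.asarray(initial_centroids, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("at least one initial centroid required")
    if x.size < c.size:
        raise ValueError("more centroids than points")
    history: list[float] = []
    assign = None
    for _ in range(max_iter):
        d2 = (x[:, None] - c[None, :]) ** 2
        new = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        present = np.unique(new)
        if present.size < c.size:
            c = c[present]
            new = np.searchsorted(present, new)
        history.append(float(((x - c[new]) ** 2).sum()))
        if assign is not None and assign.size == new.size and np.array_equal(
            assign, new
        ):
            break
        assign = new
        c = np.array([x[assign == j].mean() for j in range(c.size)])
    assert assign is not None
    populations = np.bincount(assign, minlength=c.size)
    distortion = float(((x - c[assign]) ** 2).sum())
    return ClusterModel(
        k=int(c.size),
        centroids=c,
        assignments=assign,
        populations=populations,
        distortion=distortion,
        distortion_history=history,
    )


def hkmeans(
    values,
    k: int,
    seed: int = 0,
    *,
    max_iter: int = 100,
    init_max_points: int = 2000,
) -> ClusterModel:
    """Hybrid hierarchical--K-means: Ward-cut centroids, then Lloyd."""
    cents = hierarchical_centroids(
        values, k, max_points=init_max_points, seed=seed
    )
    return kmeans_refine(values, cents, max_iter=max_iter)


# ---------------------------------------------------------------------------
# census and flag rule
# ---------------------------------------------------------------------------

def cluster_census(model: ClusterModel) -> list[tuple[int, int]]:
    """(cluster_index, population) pairs; populations sum to n."""
    return [(j, int(p)) for j, p in enumerate(model.populations)]


def flag_threshold(fold_length: int, alpha: float) -> int:
    """Maximum cluster population flaggable as implausible.

    floor(alpha * fold_length): a cluster is sparse when its population is
    at most the fraction alpha of its fold.  With the coupled configuration
    alpha = 1/fold_length this is exactly 1 (singleton clusters only).  A
    small epsilon guards the floor against the binary representation of
    rational alphas such as 1/3000.
    """
    if fold_length < 1:
        raise ValueError("fold_length must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    return int(math.floor(alpha * fold_length + 1e-9))


def flag_sparse(model: ClusterModel, threshold: int) -> np.ndarray:
    """Indices of points in clusters with population <= threshold (sorted)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0:
        return np.array([], dtype=int)
    sparse = model.populations[model.assignments] <= threshold
    return np.flatnonzero(sparse)
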