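"""Inter-patient variability metrics and fuzzy clustering of PK parameters.

Fitted per-patient parameter vectors are summarised by a small-sample
corrected coefficient of variation, CV = (1 + 1/(4n)) * sigma/mu * 100, and
grouped by fuzzy c-means (fuzzifier m = 2), with the cluster count chosen
to minimise the Fukuyama–Sugeno validity index

    V_FS = sum_i sum_j w_ij^2 ( ||x_i - c_j||^2 - ||c_j - cbar||^2 ),

which balances within-cluster compactness against centroid separation
(lower is better).  Clusters are visualised by metric multidimensional
scaling onto a plane, with the Pearson correlation between original and
embedded pairwise distances reported as projection fidelity.

Because PK rate constants span orders of magnitude, columns are scaled to
unit variance before clustering by default (raw-scale mode is retained to
probe sensitivity to this choice); CVs are always computed on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import pearsonr
from sklearn.manifold import MDS

__all__ = [
    "unbiased_cv",
    "FuzzyClusters",
    "fuzzy_cmeans",
    "fukuyama_sugeno",
    "select_cluster_count",
    "project_mds",
    "per_cluster_cv",
    "ClusterResult",
    "cluster_patients",
]


def unbiased_cv(values: Sequence[float]) -> float:
    """Nearly unbiased coefficient of variation, in percent.

    CV = (1 + 1/(4n)) * sigma/mu * 100 with the sample standard deviation;
    the correction factor tends to 1 as n grows.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    mu = x.mean()
    if mu == 0:
        raise ValueError("CV undefined for zero mean")
    sigma = x.std(ddof=1)
    return float((1.0 + 1.0 / (4.0 * n)) * sigma / mu * 100.0)


@dataclass(frozen=True)
class FuzzyClusters:
    """Raw fuzzy c-means output on one data matrix."""

    centroids: np.ndarray        # (c, d)
    memberships: np.ndarray      # (n, c), rows sum to 1
    objective: float
    n_iter: int
    seed: int

    @property
    def c(self) -> int:
        return self.centroids.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Crisp assignment by maximum membership."""
        return np.argmax(self.memberships, axis=1)


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> FuzzyClusters:
    """Fuzzy c-means with fuzzifier m = 2 by alternating optimization.

    Minimises sum_ij w_ij^2 ||x_i - c_j||^2 subject to rows of w summing
    to 1.  A point coinciding with a centroid receives crisp membership.
    The objective is nonincreasing across iterations; deterministic for a
    fixed seed (random initial memberships).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= c <= n - 1:
        raise ValueError(f"cluster count must satisfy 2 <= c <= n-1, got c={c}, n={n}")
    rng = np.random.default_rng(seed)
    w = rng.random((n, c))
    w /= w.sum(axis=1, keepdims=True)
    obj = np.inf
    for it in range(1, max_iter + 1):
        w2 = w**2
        centroids = (w2.T @ X) / w2.sum(axis=0)[:, None]
        d2 = cdist(X, centroids, "sqeuclidean")
        zero = d2 < 1e-300
        w_new = np.empty_like(w)
        inv = 1.0 / np.where(zero, 1.0, d2)
        w_new = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            w_new[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(axis=1, keepdims=True)
        new_obj = float(np.sum(w_new**2 * d2))
        shift = float(np.max(np.abs(w_new - w)))
        w = w_new
        if abs(obj - new_obj) < tol and shift < np.sqrt(tol):
            obj = new_obj
            break
        obj = new_obj
    return FuzzyClusters(centroids=centroids, memberships=w, objective=obj, n_iter=it, seed=seed)


def fukuyama_sugeno(X: np.ndarray, clusters: FuzzyClusters) -> float:
    """Fukuyama–Sugeno validity index of a fuzzy partition (lower is better)."""
    X = np.asarray(X, dtype=float)
    d2 = cdist(X, clusters.centroids, "sqeuclidean")
    cbar = clusters.centroids.mean(axis=0)
    sep = np.sum((clusters.centroids - cbar) ** 2, axis=1)  # (c,)
    return float(np.sum(clusters.memberships**2 * (d2 - sep[None, :])))


def select_cluster_count(
    X: np.ndarray,
    c_range: Sequence[int] | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[int, dict[int, float], dict[int, FuzzyClusters]]:
    """Choose the cluster count minimising V_FS over ``c_range``.

    For each candidate ``c`` the best of ``n_restarts`` seeded runs (by FCM
    objective) is kept; ties in V_FS break toward the smaller count.
    Returns (c*, {c: V_FS}, {c: best run}).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if c_range is None:
        c_range = range(2, n)
    c_range = sorted(set(int(c) for c in c_range))
    if not c_range:
        raise ValueError("empty cluster-count range")
    if c_range[0] < 2 or c_range[-1] > n - 1:
        raise ValueError("cluster counts must lie in [2, n-1]")
    vfs: dict[int, float] = {}
    best: dict[int, FuzzyClusters] = {}
    for c in c_range:
        runs = [fuzzy_cmeans(X, c, seed=seed + 1000 * r) for r in range(n_restarts)]
        best_run = min(runs, key=lambda r: r.objective)
        best[c] = best_run
        vfs[c] = fukuyama_sugeno(X, best_run)
    c_star = min(c_range, key=lambda c: (vfs[c], c))
    return c_star, vfs, best


def project_mds(X: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """Metric MDS embedding into the plane plus distance-fidelity correlation.

    Returns (coordinates (n, 2), Pearson r between original and embedded
    pairwise Euclidean distances).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least three points for a 2-D embedding")
    orig = pdist(X)
    if np.all(orig == 0):
        raise ValueError("all points coincide; embedding undefined")
    mds = MDS(n_components=2, random_state=seed, n_init=4, init="random",
              normalized_stress=False)
    coords = mds.fit_transform(X)
    emb = pdist(coords)
    r = float(pearsonr(orig, emb).statistic)
    return coords, r


def per_cluster_cv(params: pd.DataFrame, clusters: FuzzyClusters) -> dict[int, float]:
    """Mean parameter CV within each crisp cluster of 2+ patients.

    ``params`` holds raw (unstandardised) parameter values, rows = patients
    in the order used for clustering.  Singleton clusters are skipped: a CV
    cannot be assessed from one patient.
    """
    labels = clusters.labels
    out: dict[int, float] = {}
    for j in range(clusters.c):
        members = params.iloc[labels == j]
        if len(members) < 2:
            continue
        out[j] = float(np.mean([unbiased_cv(members[col].to_numpy()) for col in params.columns]))
    return out


@dataclass(frozen=True)
class ClusterResult:
    """Full clustering pipeline output for one drug's parameter matrix."""

    c: int
    clusters: FuzzyClusters
    v_fs: float
    v_fs_by_count: dict[int, float]
    projection: np.ndarray
    projection_fidelity: float
    cluster_cv_pct: dict[int, float]
    population_cv_pct: float
    standardized: bool


def cluster_patients(
    params: pd.DataFrame,
    c: int | None = None,
    standardize: bool = True,
    log_scale: bool = False,
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """Cluster patients from a patients x parameters matrix.

    Columns are scaled to unit variance before clustering when
    ``standardize`` (default); ``log_scale`` first log-transforms the
    (positive, multiplicative) rate constants so that groups differing by a
    fold-change have comparable spread.  The cluster count is selected by
    V_FS unless given.  CVs are always computed on the raw parameter scale.
    """
    if params.isna().any().any():
        raise ValueError("parameter matrix has missing cells")
    X = params.to_numpy(dtype=float)
    if log_scale:
        if (X <= 0).any():
            raise ValueError("log-scale clustering requires positive parameters")
        X = np.log(X)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = X / sd
    else:
        Xc = X
    if c is None:
        c_star, vfs, best = select_cluster_count(Xc, n_restarts=n_restarts, seed=seed)
    else:
        runs = [fuzzy_cmeans(Xc, c, seed=seed + 1000 * r) for r in range(n_restarts)]
        best_run = min(runs, key=lambda r: r.objective)
        c_star, best = c, {c: best_run}
        vfs = {c: fukuyama_sugeno(Xc, best_run)}
    clusters = best[c_star]
    coords, fidelity = project_mds(Xc, seed=seed)
    pop_cv = float(np.mean([unbiased_cv(params[col].to_numpy()) for col in params.columns]))
    return ClusterResult(
        c=c_star, clusters=clusters, v_fs=vfs[c_star], v_fs_by_count=vfs,
        projection=coords, projection_fidelity=fidelity,
        cluster_cv_pct=per_cluster_cv(params, clusters),
        population_cv_pct=pop_cv, standardized=standardize,
    )
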