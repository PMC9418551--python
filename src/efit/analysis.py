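"""Structural validation: dissimilarity matrices, PAM (k-medoids)
clustering with silhouette-based selection of k, and per-group squared
Pearson correlation of Ecosystem Fit against observed productivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = ("mat", "map", "gseason")


@dataclass(frozen=True)
class ClusterModel:
    k: int
    medoid_ids: tuple[str, ...]
    assignment: dict[str, int]
    avg_silhouette: float
    variables_used: tuple[str, ...]
    total_cost: float

    def labels(self, ids) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids], dtype=int)


def dissimilarity_matrix(
    features: pd.DataFrame, standardize: bool = True
) -> pd.DataFrame:
    """Pairwise Euclidean distances between per-site feature vectors.

    Rows with any missing feature are excluded (reported via warning).
    With ``standardize`` each feature is z-scored first; zero-variance
    features are dropped with a warning rather than producing NaNs.
    """
    df = features.apply(pd.to_numeric)
    complete = df.dropna()
    dropped = df.index.difference(complete.index)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} site(s) excluded for missing features: "
            f"{list(map(str, dropped[:10]))}"
        )
    if len(complete) < 2:
        raise ValueError("need at least 2 sites with complete features")
    values = complete.to_numpy(dtype=float)
    cols = list(complete.columns)
    if standardize:
        sd = values.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            bad = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"zero-variance feature(s) dropped: {bad}")
            values = values[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
            sd = sd[keep]
        if not cols:
            raise ValueError("no features left after dropping zero-variance ones")
        values = (values - values.mean(axis=0)) / sd
    dist = squareform(pdist(values, metric="euclidean"))
    return pd.DataFrame(dist, index=complete.index, columns=complete.index)


def _as_matrix(dist: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), list(dist.index)
    arr = np.asarray(dist, dtype=float)
    return arr, list(range(arr.shape[0]))


def _assign(dmat: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = dmat[:, medoids]
    labels = np.argmin(sub, axis=1)
    cost = float(sub[np.arange(len(dmat)), labels].sum())
    return labels, cost


def _pam_build(dmat: np.ndarray, k: int) -> list[int]:
    n = len(dmat)
    medoids = [int(np.argmin(dmat.sum(axis=0)))]
    while len(medoids) < k:
        nearest = dmat[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = float(np.maximum(nearest - dmat[:, j], 0.0).sum())
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    return medoids


def _swap_descent(dmat: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Steepest-descent SWAP phase: repeatedly apply the medoid/non-medoid
    exchange that most reduces total distance-to-medoid."""
    n = len(dmat)
    medoids = np.array(sorted(medoids), dtype=int)
    _, cost = _assign(dmat, medoids)
    while True:
        best_delta = -1e-12  # strict improvement required
        best_swap: tuple[int, int] | None = None
        medoid_set = set(medoids.tolist())
        for mi, _m in enumerate(medoids):
            for h in range(n):
                if h in medoid_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                _, trial_cost = _assign(dmat, trial)
                delta = trial_cost - cost
                if delta < best_delta:
                    best_delta = delta
                    best_swap = (mi, h)
        if best_swap is None:
            return medoids, cost
        mi, h = best_swap
        medoids[mi] = h
        medoids = np.array(sorted(medoids), dtype=int)
        _, cost = _assign(dmat, medoids)


def pam_cluster(
    dist: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    variables_used: tuple[str, ...] = (),
    n_restarts: int = 10,
) -> ClusterModel:
    """Partitioning around medoids: greedy BUILD then steepest-descent SWAP.

    The SWAP descent from the BUILD initialization can stall in a
    single-exchange local optimum, so ``n_restarts`` additional descents
    from seeded random medoid sets are run and the lowest-cost solution is
    kept.  Ties break toward lower row indices; given the same seed the
    result is fully deterministic.
    """
    dmat, ids = _as_matrix(dist)
    n = len(dmat)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n={n}, got {k}")

    starts = [np.array(_pam_build(dmat, k), dtype=int)]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        starts.append(rng.choice(n, size=k, replace=False))

    best_medoids: np.ndarray | None = None
    best_cost = np.inf
    for start in starts:
        medoids_i, cost_i = _swap_descent(dmat, start)
        if cost_i < best_cost - 1e-12 or (
            abs(cost_i - best_cost) <= 1e-12
            and best_medoids is not None
            and tuple(medoids_i) < tuple(best_medoids)
        ):
            best_medoids, best_cost = medoids_i, cost_i
    medoids, cost = best_medoids, best_cost
    labels, _ = _assign(dmat, medoids)

    sil = average_silhouette(dmat, labels)
    return ClusterModel(
        k=k,
        medoid_ids=tuple(ids[m] for m in medoids),
        assignment={ids[i]: int(labels[i]) for i in range(n)},
        avg_silhouette=sil,
        variables_used=tuple(variables_used),
        total_cost=cost,
    )


def average_silhouette(dmat: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width s(i) = (b - a) / max(a, b) over all points.

    Points in singleton clusters get s = 0 by convention.
    """
    n = len(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            scores[i] = 0.0
            continue
        a = dmat[i, own].sum() / (n_own - 1)
        b = min(
            dmat[i, labels == c].mean() for c in uniq if c != labels[i]
        )
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def select_k(
    dist: pd.DataFrame | np.ndarray,
    k_range,
    seed: int = 0,
    variables_used: tuple[str, ...] = (),
) -> tuple[ClusterModel, pd.DataFrame]:
    """Fit PAM for each k and keep the model with the largest average
    silhouette width.  Returns (best model, per-k summary table)."""
    dmat, _ = _as_matrix(dist)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 2 or ks[-1] >= len(dmat):
        raise ValueError(f"k_range must lie within [2, n-1]; got {ks}")
    models = [pam_cluster(dist, k, seed, variables_used) for k in ks]
    summary = pd.DataFrame(
        {
            "k": ks,
            "avg_silhouette": [m.avg_silhouette for m in models],
            "total_cost": [m.total_cost for m in models],
        }
    )
    best = max(models, key=lambda m: m.avg_silhouette)
    return best, summary


def groupwise_r2(
    results: pd.DataFrame,
    group_by: str,
    x: str = "tnpp_obs",
    y: str = "efit",
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-group squared Pearson correlation of y against x.

    Groups with fewer than ``min_n`` complete pairs are skipped with a log
    note; zero variance in either variable yields NaN r2 and a flag.
    Columns: group, n, r2, mean_x, mean_y, flag.
    """
    if group_by not in results.columns:
        raise KeyError(f"no column '{group_by}' in results")
    rows = []
    for group, sub in results.groupby(group_by, dropna=True):
        sub = sub[[x, y]].dropna()
        if len(sub) < min_n:
            logger.info("group %r skipped: only %d complete pairs", group, len(sub))
            continue
        xv = sub[x].to_numpy(dtype=float)
        yv = sub[y].to_numpy(dtype=float)
        flag = ""
        if np.std(xv) == 0 or np.std(yv) == 0:
            r2 = np.nan
            flag = "zero_variance"
        else:
            r2 = float(np.corrcoef(xv, yv)[0, 1] ** 2)
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "r2": r2,
                f"mean_{x}": float(xv.mean()),
                f"mean_{y}": float(yv.mean()),
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
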