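"""Distances and the clustering battery applied to protein profiles.

Four families of algorithms, mirroring common practice for expression-profile
data: agglomerative hierarchical clustering (single, complete, average and
Ward linkage), K-means (Lloyd iterations with centers initialized by random
sampling from the data), neural gas (online vector quantization with a
rank-based neighborhood and annealed learning rate), and fuzzy C-means
(probabilistic memberships, hardened to the maximal-membership cluster for
comparison with the other methods).

Distances: Euclidean, or ``1 - r`` for centered / uncentered (cosine)
Pearson correlation.  Missing profile cells are not tolerated here — filter
or impute first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist, pdist, squareform

from .profiles import ProfileMatrix

__all__ = [
    "DistanceMatrix",
    "MergeTree",
    "ClusteringResult",
    "euclidean_distance",
    "correlation_distance",
    "pairwise_distances",
    "hca",
    "cut_tree",
    "merge_distance_curve",
    "kmeans",
    "neural_gas",
    "fuzzy_cmeans",
    "cluster_rows",
]

LINKAGES = ("single", "complete", "average", "ward")
METRICS = ("euclidean", "pearson_centered", "pearson_uncentered")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between protein profiles."""

    ids: list[str]
    d: np.ndarray
    metric_tag: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T) or (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.nanmin(self.d) < 0:
            raise ValueError("distances must be non-negative")
        if self.metric_tag not in METRICS:
            raise ValueError(f"unknown metric {self.metric_tag!r}")


@dataclass
class MergeTree:
    """Agglomeration history in scipy linkage-matrix form (n-1 merges)."""

    Z: np.ndarray
    n: int
    linkage_tag: str
    metric_tag: str

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (self.n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows")

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


@dataclass
class ClusteringResult:
    """A hard partition with provenance; soft methods add memberships."""

    labels: np.ndarray
    k: int
    method: dict = field(default_factory=dict)
    centers: np.ndarray | None = None
    membership: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")
        if self.membership is not None:
            colsum = self.membership.sum(axis=0)
            if not np.allclose(colsum, 1.0):
                raise ValueError("membership columns must sum to 1")


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Euclidean distance between two condition vectors."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(((x - y) ** 2).sum()))


def correlation_distance(x: np.ndarray, y: np.ndarray, centered: bool = True) -> float:
    """Correlation distance d = 1 - r in [0, 2].

    ``centered`` uses Pearson's correlation; otherwise the uncentered
    (cosine) form.  Degenerate input (zero variance / zero norm) yields NaN,
    to be excluded downstream.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need vectors of length >= 2")
    if centered:
        x = x - x.mean()
        y = y - y.mean()
    nx, ny = np.sqrt((x ** 2).sum()), np.sqrt((y ** 2).sum())
    if nx == 0.0 or ny == 0.0:
        return np.nan
    r = float(np.dot(x, y) / (nx * ny))
    return 1.0 - max(-1.0, min(1.0, r))


def pairwise_distances(matrix: ProfileMatrix | np.ndarray, metric: str = "euclidean",
                       ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Full pairwise DistanceMatrix over profile rows."""
    if isinstance(matrix, ProfileMatrix):
        X = matrix.values
        ids = list(matrix.protein_ids)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
    if np.isnan(X).any():
        raise ValueError("profile matrix contains missing cells; filter or impute first")
    scipy_metric = {"euclidean": "euclidean", "pearson_centered": "correlation",
                    "pearson_uncentered": "cosine"}[metric]
    d = squareform(np.maximum(pdist(X, metric=scipy_metric), 0.0))
    return DistanceMatrix(ids=ids, d=d, metric_tag=metric)


def hca(dm: DistanceMatrix, linkage: str = "ward") -> MergeTree:
    """Agglomerative hierarchical clustering via Lance-Williams updates.

    Ward linkage is only meaningful on Euclidean distances (heights are the
    square root of the variance-increase recurrence applied to squared
    distances, the standard convention) and is rejected for correlation
    metrics.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and dm.metric_tag != "euclidean":
        raise ValueError("ward linkage requires euclidean distances")
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains NaN entries")
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two items")
    Z = sch.linkage(squareform(dm.d, checks=False), method=linkage)
    return MergeTree(Z=Z, n=n, linkage_tag=linkage, metric_tag=dm.metric_tag)


def cut_tree(tree: MergeTree, k: int) -> ClusteringResult:
    """Horizontal cut: the partition left after n - k merges.

    Labels are renumbered by first appearance so results are deterministic
    and comparable across methods.
    """
    if not 1 <= k <= tree.n:
        raise ValueError(f"k must lie in [1, {tree.n}]")
    raw = sch.cut_tree(tree.Z, n_clusters=k).ravel()
    return ClusteringResult(
        labels=_relabel_first_appearance(raw), k=k,
        method={"algorithm": "hca", "linkage": tree.linkage_tag,
                "distance": tree.metric_tag, "k": k},
    )


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def merge_distance_curve(tree: MergeTree) -> tuple[np.ndarray, np.ndarray, int | None]:
    """(k, merge height) pairs plus a knee estimate.

    For each cluster number k from n-1 down to 1, the height of the merge
    that produced k clusters.  The knee is the k maximizing the second
    difference of heights along decreasing k (needs at least three points),
    a numerical proxy for the visual jump in the merge-distance plot.
    """
    n = tree.n
    ks = np.arange(n - 1, 0, -1)
    heights = tree.heights  # merge j (0-based) produces n - j - 1 clusters
    curve = heights[(n - ks) - 1]
    knee = None
    if ks.size >= 3:
        # h as a function of decreasing k: h(ks[i]) = curve[i]
        second = curve[2:] - 2 * curve[1:-1] + curve[:-2]
        knee = int(ks[1:-1][int(np.argmax(second))])
    return ks, curve, knee


def _init_centers(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Initial centers sampled uniformly without replacement from the data."""
    return X[rng.choice(X.shape[0], size=k, replace=False)].copy()


def kmeans(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 300,
           n_init: int = 10) -> ClusteringResult:
    """Lloyd's K-means with data-sampled random initialization and restarts.

    Each start samples k centers from the data, then iterates nearest-center
    assignment and mean updates until the assignment reaches a fixpoint (or
    ``max_iter``); of ``n_init`` starts the one with the lowest within-cluster
    sum of squares is kept (single-start Lloyd is notoriously init-sensitive;
    set ``n_init=1`` to expose that sensitivity, as the reproducibility
    protocol does).  The objective is checked to be non-increasing on every
    iteration.  An emptied cluster is re-seeded from the datum farthest from
    its assigned center (recorded in the provenance).
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if n_init > 1:
        rng = np.random.default_rng(seed)
        best: ClusteringResult | None = None
        for _ in range(n_init):
            run = kmeans(X, k, seed=int(rng.integers(2 ** 31)), max_iter=max_iter, n_init=1)
            if best is None or run.method["objective"] < best.method["objective"]:
                best = run
        assert best is not None
        best.method.update(seed=seed, n_init=n_init)
        return best
    X = _as_clusterable(X, k)
    rng = np.random.default_rng(seed)
    centers = _init_centers(X, k, rng)
    labels = np.full(X.shape[0], -1)
    prev_obj = np.inf
    reseeds = 0
    for iteration in range(max_iter):
        dist2 = cdist(X, centers, metric="sqeuclidean")
        new_labels = dist2.argmin(axis=1)
        reseeded = False
        empty = [j for j in range(k) if not (new_labels == j).any()]
        if empty:
            # re-seed each empty cluster from a distinct high-cost datum
            contrib = dist2[np.arange(X.shape[0]), new_labels]
            order = iter(np.argsort(contrib)[::-1])
            for j in empty:
                farthest = int(next(order))
                centers[j] = X[farthest]
                new_labels[farthest] = j
                reseeds += 1
            reseeded = True
        if reseeded:
            dist2 = cdist(X, centers, metric="sqeuclidean")
            prev_obj = np.inf  # re-seeding restarts the descent
        obj = float(dist2[np.arange(X.shape[0]), new_labels].sum())
        if obj > prev_obj + 1e-9 * max(1.0, prev_obj):
            raise RuntimeError("k-means objective increased; numerical inconsistency")
        prev_obj = obj
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if members.size:  # a re-seed cascade may still empty a singleton
                centers[j] = members.mean(axis=0)
    return ClusteringResult(
        labels=labels, k=k, centers=centers,
        method={"algorithm": "kmeans", "k": k, "seed": seed, "n_init": 1,
                "iterations": iteration + 1, "objective": prev_obj,
                "empty_cluster_reseeds": reseeds},
    )


def neural_gas(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    epochs: int = 50,
    eps_start: float = 0.5,
    eps_end: float = 0.005,
    lambda_start: float | None = None,
    lambda_end: float = 0.01,
) -> ClusteringResult:
    """Neural-gas vector quantization with rank-based neighborhood.

    For every presented profile all k centers are ranked by distance; the
    center of rank r moves toward the datum by eps(t) * exp(-r / lambda(t)).
    Both eps and lambda decay exponentially from their start to end values
    over ``epochs * n`` presentations (the schedule of the original
    formulation; ``lambda_start`` defaults to k / 2).  Hard labels are the
    nearest centers after training.
    """
    X = _as_clusterable(X, k)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    lam_start = k / 2.0 if lambda_start is None else lambda_start
    centers = _init_centers(X, k, rng)
    t_max = max(1, epochs * n)
    t = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = t / t_max
            eps = eps_start * (eps_end / eps_start) ** frac
            lam = lam_start * (lambda_end / lam_start) ** frac
            delta = X[i] - centers
            ranks = np.argsort(np.argsort((delta ** 2).sum(axis=1)))
            centers += (eps * np.exp(-ranks / lam))[:, None] * delta
            t += 1
    labels = cdist(X, centers, metric="sqeuclidean").argmin(axis=1)
    return ClusteringResult(
        labels=labels, k=k, centers=centers,
        method={"algorithm": "neural_gas", "k": k, "seed": seed, "epochs": epochs,
                "eps": (eps_start, eps_end), "lambda": (lam_start, lambda_end)},
    )


def fuzzy_cmeans(
    X: np.ndarray,
    k: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> ClusteringResult:
    """Fuzzy C-means with fuzzifier m and maximal-membership hardening.

    Memberships u_ij are proportional to (1 / d_ij^2)^(1 / (m-1)), normalized
    per profile; centers are membership^m-weighted means.  Iteration stops
    when the largest center shift falls below ``tol``.  A profile coinciding
    with a center receives membership 1 for that center.  Hard labels take
    the maximal membership (ties to the lowest cluster index).
    """
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")
    X = _as_clusterable(X, k)
    rng = np.random.default_rng(seed)
    centers = _init_centers(X, k, rng)
    exponent = 1.0 / (m - 1.0)
    U = np.empty((k, X.shape[0]))
    for _ in range(max_iter):
        d2 = cdist(centers, X, metric="sqeuclidean")  # (k, n)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d2 ** -exponent
            U = w / w.sum(axis=0, keepdims=True)
        coincident = zero.any(axis=0)
        if coincident.any():
            U[:, coincident] = 0.0
            first_zero = zero[:, coincident].argmax(axis=0)
            U[first_zero, np.flatnonzero(coincident)] = 1.0
        um = U ** m
        new_centers = (um @ X) / um.sum(axis=1, keepdims=True)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    labels = U.argmax(axis=0)  # argmax breaks ties toward the lowest index
    return ClusteringResult(
        labels=labels, k=k, centers=centers, membership=U,
        method={"algorithm": "fuzzy_cmeans", "k": k, "seed": seed, "m": m, "tol": tol},
    )


def _as_clusterable(X: np.ndarray | ProfileMatrix, k: int) -> np.ndarray:
    if isinstance(X, ProfileMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise ValueError("profiles contain missing cells; filter or impute first")
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must lie in [1, {X.shape[0]}]")
    return X


def cluster_rows(X: np.ndarray, k: int, method: Mapping[str, object], seed: int = 0) -> ClusteringResult:
    """Dispatch a clustering run from a method descriptor.

    ``method`` needs an ``algorithm`` key: one of the four linkages,
    ``kmeans``, ``neural_gas`` / ``neuralgas``, or ``fuzzy_cmeans`` / ``fcm``;
    hierarchical methods honor a ``distance`` key (default euclidean).
    """
    algorithm = str(method.get("algorithm", "ward"))
    if algorithm in LINKAGES:
        dm = pairwise_distances(X, metric=str(method.get("distance", "euclidean")))
        result = cut_tree(hca(dm, linkage=algorithm), k)
        result.method["seed"] = seed
        return result
    if algorithm == "kmeans":
        return kmeans(X, k, seed=seed, n_init=int(method.get("n_init", 10)))
    if algorithm in ("neural_gas", "neuralgas"):
        kwargs = {key: method[key] for key in ("epochs",) if key in method}
        return neural_gas(X, k, seed=seed, **kwargs)
    if algorithm in ("fuzzy_cmeans", "fcm"):
        return fuzzy_cmeans(X, k, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")
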