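"""Evaluation of clustering results: agreement, reproducibility, validity.

Partition agreement uses pair counting: the Rand index is the fraction of
item pairs on which two partitions agree (both together or both apart), and
the adjusted Rand index (ARI) is its chance-corrected form via the
contingency-table formula, so that independent random partitions score ~0
and identical partitions score exactly 1.

Reproducibility of seed-sensitive algorithms is probed by re-running the
same algorithm repeatedly (classically 25 runs at a fixed cluster number of
20, each initialized from data sampled anew) and collecting all pairwise
similarities; two algorithms are then compared by a rank-sum test on their
off-diagonal similarity values.

The "true" number of clusters is probed by sweeping the cluster number and
scoring each partition with the Calinski-Harabasz index, Index I, the
Davies-Bouldin index (in Halkidi's sum-of-squares instance), the
Krzanowski-Lai index, and the leave-one-condition-out Figure of Merit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as st
from scipy.spatial.distance import cdist

from .cluster import ClusteringResult, cluster_rows
from .profiles import ProfileMatrix

__all__ = [
    "RandMatrix",
    "IndexCurve",
    "AlgorithmComparison",
    "rand_index",
    "adjusted_rand_index",
    "random_partition",
    "mean_ari_random_partitions",
    "reproducibility_protocol",
    "compare_reproducibility",
    "figure_of_merit",
    "within_ss",
    "calinski_harabasz",
    "index_I",
    "davies_bouldin",
    "krzanowski_lai",
    "index_sweep",
    "algorithm_similarity_matrix",
]

#: algorithms whose outcome depends on the seed (re-run protocols apply)
STOCHASTIC_ALGORITHMS = ("kmeans", "neural_gas", "neuralgas", "fuzzy_cmeans", "fcm")


@dataclass
class RandMatrix:
    """Pairwise similarity between repeated clustering runs."""

    runs: list[dict]
    matrix: np.ndarray
    measure_tag: str  # "rand" | "adjusted_rand"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        r = len(self.runs)
        if self.matrix.shape != (r, r):
            raise ValueError("similarity matrix shape does not match run count")
        if not np.allclose(self.matrix, self.matrix.T) or not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("similarity matrix must be symmetric with unit diagonal")

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]


@dataclass
class IndexCurve:
    """A validity index evaluated over a cluster-number sweep."""

    name: str
    rule: str  # "maximize" | "minimize"
    ks: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ks = np.asarray(self.ks, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.ks.shape != self.values.shape:
            raise ValueError("ks and values must align")
        if (np.diff(self.ks) <= 0).any():
            raise ValueError("ks must be strictly increasing")
        if self.rule not in ("maximize", "minimize"):
            raise ValueError(f"unknown optimum rule {self.rule!r}")

    def optimum(self) -> int | None:
        """The k selected by this index (None if every value is NA)."""
        finite = np.isfinite(self.values)
        if not finite.any():
            return None
        vals = np.where(finite, self.values, -np.inf if self.rule == "maximize" else np.inf)
        pick = np.argmax(vals) if self.rule == "maximize" else np.argmin(vals)
        return int(self.ks[pick])


@dataclass
class AlgorithmComparison:
    """Reproducibility contrast between two algorithms' run batteries."""

    methods: tuple[dict, dict]
    means: tuple[float, float]
    sds: tuple[float, float]
    statistic: float
    pvalue: float
    lower: int  # index (0/1) of the method with the lower mean similarity

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value out of [0, 1]")


def _check_pair(a: Sequence[int], b: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D of equal length")
    if a.size < 2:
        raise ValueError("need at least two items")
    return a, b


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1.0) / 2.0


def rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Fraction of item pairs on which two partitions agree (in [0, 1])."""
    a, b = _check_pair(a, b)
    table = _contingency(a, b)
    n = a.size
    total = _comb2(np.array(n))
    same_same = _comb2(table).sum()
    same_a = _comb2(table.sum(axis=1)).sum()
    same_b = _comb2(table.sum(axis=0)).sum()
    agreements = total + 2.0 * same_same - same_a - same_b
    return float(agreements / total)


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Chance-corrected Rand index (<= 1; ~0 for independent partitions).

    Computed from the contingency table as (observed - expected) /
    (max - expected).  When the denominator degenerates (both partitions
    all-singletons or both one single cluster) the value is 1.0 if the
    partitions are identical as set partitions, else 0.0.
    """
    a, b = _check_pair(a, b)
    table = _contingency(a, b)
    n = a.size
    sum_nij = _comb2(table).sum()
    sum_ai = _comb2(table.sum(axis=1)).sum()
    sum_bj = _comb2(table.sum(axis=0)).sum()
    total = _comb2(np.array(n))
    expected = sum_ai * sum_bj / total
    maximum = 0.5 * (sum_ai + sum_bj)
    if maximum == expected:
        return 1.0 if sum_nij == maximum else 0.0
    return float((sum_nij - expected) / (maximum - expected))


def random_partition(n_items: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random assignment of items to groups."""
    return rng.integers(0, n_groups, size=n_items)


def mean_ari_random_partitions(
    n_items: int = 200, n_groups: int = 5, n_pairs: int = 1000, seed: int = 0
) -> float:
    """Mean ARI over independently drawn uniform random partition pairs.

    Simulation check of the no-similarity anchor: for unrelated partitions
    the adjusted Rand index is centered on zero.
    """
    rng = np.random.default_rng(seed)
    values = [
        adjusted_rand_index(
            random_partition(n_items, n_groups, rng),
            random_partition(n_items, n_groups, rng),
        )
        for _ in range(n_pairs)
    ]
    return float(np.mean(values))


def derive_seed(master_seed: int, *parts: object) -> int:
    """Deterministic, platform-stable child seed below 2^31."""
    payload = ":".join([str(master_seed), *map(str, parts)])
    return zlib.crc32(payload.encode()) & 0x7FFFFFFF


def _similarity(a: np.ndarray, b: np.ndarray, measure: str) -> float:
    if measure == "rand":
        return rand_index(a, b)
    if measure == "adjusted_rand":
        return adjusted_rand_index(a, b)
    raise ValueError(f"unknown measure {measure!r}")


def reproducibility_protocol(
    X: np.ndarray | ProfileMatrix,
    method: Mapping[str, object],
    k: int = 20,
    reps: int = 25,
    seed: int = 0,
    measure: str = "rand",
) -> RandMatrix:
    """Repeated-run similarity matrix for a seed-sensitive algorithm.

    The algorithm is run ``reps`` times at fixed cluster number ``k``, each
    run initialized with centers sampled from the data under a child seed
    derived from the master seed; every pair of runs is scored with the
    chosen similarity measure.  Deterministic (hierarchical) algorithms are
    rejected: re-running them is meaningless.
    """
    algorithm = str(method.get("algorithm", ""))
    if algorithm not in STOCHASTIC_ALGORITHMS:
        raise ValueError(f"algorithm {algorithm!r} is deterministic; protocol not applicable")
    method = dict(method)
    if algorithm == "kmeans":
        # the protocol probes single-start sensitivity: centers are sampled
        # anew in each repetition, so restarts are off unless asked for
        method.setdefault("n_init", 1)
    X = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    runs, labelings = [], []
    for r in range(reps):
        child = derive_seed(seed, algorithm, k, r)
        result = cluster_rows(X, k, method, seed=child)
        runs.append({"algorithm": algorithm, "k": k, "rep": r, "seed": child})
        labelings.append(result.labels)
    matrix = np.eye(reps)
    for i in range(reps):
        for j in range(i + 1, reps):
            matrix[i, j] = matrix[j, i] = _similarity(labelings[i], labelings[j], measure)
    return RandMatrix(runs=runs, matrix=matrix, measure_tag=measure)


def compare_reproducibility(m1: RandMatrix, m2: RandMatrix) -> AlgorithmComparison:
    """Two-sided rank-sum contrast of two off-diagonal similarity sets.

    Off-diagonal pairwise values are not independent samples (each run
    enters many pairs), so the p-value is an approximation, as in the
    original protocol.
    """
    if m1.matrix.shape != m2.matrix.shape or m1.measure_tag != m2.measure_tag:
        raise ValueError("batteries must share shape and similarity measure")
    v1, v2 = m1.off_diagonal(), m2.off_diagonal()
    if np.array_equal(np.sort(v1), np.sort(v2)):
        stat, p = float(v1.size * v2.size / 2.0), 1.0
    else:
        res = st.mannwhitneyu(v1, v2, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    means = (float(v1.mean()), float(v2.mean()))
    return AlgorithmComparison(
        methods=(m1.runs[0], m2.runs[0]),
        means=means,
        sds=(float(v1.std(ddof=1)), float(v2.std(ddof=1))),
        statistic=stat,
        pvalue=p,
        lower=int(np.argmin(means)),
    )


def within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean deviations from centroids."""
    X = np.asarray(X, dtype=float)
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        total += ((members - members.mean(axis=0)) ** 2).sum()
    return float(total)


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio index [B/(k-1)] / [W/(n-k)]; larger is better.

    NaN when the partition is degenerate (k < 2, k > n-1, an empty cluster
    label range, or zero within-cluster scatter).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    k = np.unique(labels).size
    if not 2 <= k <= n - 1:
        return np.nan
    w = within_ss(X, labels)
    grand = X.mean(axis=0)
    b = sum(
        (labels == lab).sum() * ((X[labels == lab].mean(axis=0) - grand) ** 2).sum()
        for lab in np.unique(labels)
    )
    if w <= 0.0:
        return np.nan
    return float((b / (k - 1)) / (w / (n - k)))


def index_I(X: np.ndarray, labels: np.ndarray, power: float = 2.0) -> float:
    """Index I: ((1/k) * (E1/Ek) * Dk)^p; larger is better.

    E terms are summed Euclidean distances of points to their (global or
    cluster) center; Dk is the largest inter-center distance.  Defined for
    k >= 2; NaN when Ek degenerates to zero.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        return np.nan
    grand = X.mean(axis=0)
    e1 = np.sqrt(((X - grand) ** 2).sum(axis=1)).sum()
    centers = np.vstack([X[labels == lab].mean(axis=0) for lab in uniq])
    ek = sum(
        np.sqrt(((X[labels == lab] - centers[i]) ** 2).sum(axis=1)).sum()
        for i, lab in enumerate(uniq)
    )
    if ek <= 0.0:
        return np.nan
    dk = cdist(centers, centers).max()
    return float(((1.0 / k) * (e1 / ek) * dk) ** power)


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index with RMS intra-cluster dispersion; smaller is better.

    s_i is the root-mean-squared distance of cluster members to their
    centroid (the error-sum-of-squares instance); cluster similarity is
    (s_i + s_j) / d(c_i, c_j).  NaN for coincident centroids.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        return np.nan
    centers = np.vstack([X[labels == lab].mean(axis=0) for lab in uniq])
    s = np.array([
        np.sqrt(((X[labels == lab] - centers[i]) ** 2).sum(axis=1).mean())
        for i, lab in enumerate(uniq)
    ])
    d = cdist(centers, centers)
    if (d[np.triu_indices(k, k=1)] == 0.0).any():
        return np.nan
    ratios = (s[:, None] + s[None, :]) / np.where(d > 0, d, np.inf)
    np.fill_diagonal(ratios, -np.inf)
    return float(ratios.max(axis=1).mean())


def krzanowski_lai(w_by_k: Mapping[int, float], k: int, n_features: int) -> float:
    """Krzanowski-Lai index KL(k) = |DIFF(k)| / |DIFF(k+1)|; larger is better.

    DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k) with p the feature count;
    requires W at k-1, k and k+1 from the same algorithm and dataset.  NaN
    when a W value is unavailable or DIFF(k+1) vanishes.
    """
    if k < 2:
        return np.nan
    needed = (k - 1, k, k + 1)
    if any(j not in w_by_k or not np.isfinite(w_by_k[j]) for j in needed):
        return np.nan
    p = float(n_features)

    def diff(j: int) -> float:
        return (j - 1) ** (2.0 / p) * w_by_k[j - 1] - j ** (2.0 / p) * w_by_k[j]

    denom = abs(diff(k + 1))
    if denom == 0.0:
        return np.nan
    return float(abs(diff(k)) / denom)


def figure_of_merit(
    X: np.ndarray | ProfileMatrix,
    method: Mapping[str, object],
    k_range: Sequence[int],
    seed: int = 0,
    adjusted: bool = True,
) -> IndexCurve:
    """Leave-one-condition-out Figure of Merit curve; smaller is better.

    For each left-out condition e the rows are clustered on the remaining
    conditions; FOM(e, k) is the root-mean-squared deviation of each row's
    value in e from its cluster's mean in e, and FOM(k) sums over all e.
    The adjusted form divides by sqrt((n - k) / n) to correct the downward
    drift with growing k.  k > n yields NA, as does the adjusted form at
    k = n (raw FOM is exactly zero there: every singleton predicts itself).
    """
    X = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    n, n_cond = X.shape
    if n_cond < 2:
        raise ValueError("figure of merit needs at least two conditions")
    ks = np.asarray(sorted(int(k) for k in k_range), dtype=int)
    values = np.full(ks.shape, np.nan)
    for ki, k in enumerate(ks):
        if k > n or (adjusted and k == n):
            continue
        fom = 0.0
        for e in range(n_cond):
            rest = np.delete(X, e, axis=1)
            child = derive_seed(seed, "fom", str(method.get("algorithm")), k, e)
            labels = cluster_rows(rest, k, method, seed=child).labels
            sq = 0.0
            for lab in np.unique(labels):
                col = X[labels == lab, e]
                sq += ((col - col.mean()) ** 2).sum()
            fom += np.sqrt(sq / n)
        if adjusted:
            fom /= np.sqrt((n - k) / n)
        values[ki] = fom
    return IndexCurve(name="fom_adjusted" if adjusted else "fom", rule="minimize",
                      ks=ks, values=values)


#: sweepable partition indexes: name -> (function, optimum rule)
PARTITION_INDEXES = {
    "calinski_harabasz": (calinski_harabasz, "maximize"),
    "index_i": (index_I, "maximize"),
    "davies_bouldin": (davies_bouldin, "minimize"),
}


def index_sweep(
    X: np.ndarray | ProfileMatrix,
    method: Mapping[str, object],
    k_range: Sequence[int],
    indexes: Sequence[str] = ("calinski_harabasz", "index_i", "davies_bouldin", "krzanowski_lai"),
    seed: int = 0,
) -> dict[str, IndexCurve]:
    """Evaluate validity indexes over one clustering per cluster number.

    The run at cluster number k uses a child seed derived from (master seed,
    algorithm, k), so curves are reproducible and runs independent.  The
    Krzanowski-Lai index consumes the within-SS sequence of the sweep (with
    W(1), the total sum of squares, supplied analytically); per-k failures
    are recorded as NA and the sweep continues.
    """
    X = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    n, n_features = X.shape
    ks = np.asarray(sorted(int(k) for k in k_range), dtype=int)
    if ks.size == 0 or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    labelings: dict[int, np.ndarray] = {}
    w_by_k: dict[int, float] = {1: within_ss(X, np.zeros(n, dtype=int))}
    for k in ks:
        child = derive_seed(seed, str(method.get("algorithm")), k)
        try:
            labels = cluster_rows(X, int(k), method, seed=child).labels
            labelings[int(k)] = labels
            w_by_k[int(k)] = within_ss(X, labels)
        except (ValueError, RuntimeError):
            continue
    curves: dict[str, IndexCurve] = {}
    for name in indexes:
        if name == "krzanowski_lai":
            values = np.array([krzanowski_lai(w_by_k, int(k), n_features) for k in ks])
            curves[name] = IndexCurve(name=name, rule="maximize", ks=ks, values=values)
            continue
        fn, rule = PARTITION_INDEXES[name]
        values = np.array([
            fn(X, labelings[int(k)]) if int(k) in labelings else np.nan for k in ks
        ])
        curves[name] = IndexCurve(name=name, rule=rule, ks=ks, values=values)
    return curves


def algorithm_similarity_matrix(
    X: np.ndarray | ProfileMatrix,
    methods: Sequence[Mapping[str, object]],
    k_range: Sequence[int],
    seed: int = 0,
    measure: str = "adjusted_rand",
) -> tuple[np.ndarray, list[dict]]:
    """Mean cross-algorithm partition similarity over a cluster-number sweep.

    For every pair of methods and every k, both methods' k-cluster partitions
    are compared (adjusted Rand by default); each cell holds the mean over k.
    The diagonal is 1 by definition.
    """
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    X = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    ks = [int(k) for k in sorted(k_range)]
    labelings = []
    for method in methods:
        per_k = {}
        for k in ks:
            child = derive_seed(seed, str(method.get("algorithm")), str(method.get("distance", "")), k)
            per_k[k] = cluster_rows(X, k, method, seed=child).labels
        labelings.append(per_k)
    m = len(methods)
    matrix = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            sims = [_similarity(labelings[i][k], labelings[j][k], measure) for k in ks]
            matrix[i, j] = matrix[j, i] = float(np.mean(sims))
    return matrix, [dict(method) for method in methods]
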