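"""Independent brute-force oracles used by several test modules.

Everything here is deliberately naive (quadratic/cubic loops, direct
formulas) and shares no code with the package's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_hca(d: np.ndarray, linkage: str) -> tuple[list[float], np.ndarray]:
    """O(n^3) agglomeration by re-scanning the full distance matrix.

    Returns the merge heights in order and the cophenetic distance matrix
    (the height at which each pair first shares a cluster).  Ward expects
    Euclidean input distances and applies the Lance-Williams variance-
    increase recurrence on squared distances, reporting square-rooted
    heights.
    """
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d[i, j])
    heights: list[float] = []
    coph = np.zeros((n, n))
    next_id = n

    def get(a: int, b: int) -> float:
        return dist[(min(a, b), max(a, b))]

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            cand = (get(a, b), a, b)
            if best is None or cand < best:
                best = cand
        h, a, b = best
        heights.append(h)
        members_a, members_b = clusters.pop(a), clusters.pop(b)
        merged = members_a + members_b
        for i in members_a:
            for j in members_b:
                coph[i, j] = coph[j, i] = h
        na, nb = len(members_a), len(members_b)
        for c in list(clusters):
            dac, dbc = get(a, c), get(b, c)
            nc = len(clusters[c])
            if linkage == "single":
                new = min(dac, dbc)
            elif linkage == "complete":
                new = max(dac, dbc)
            elif linkage == "average":
                new = (na * dac + nb * dbc) / (na + nb)
            elif linkage == "ward":
                new = np.sqrt(
                    ((na + nc) * dac ** 2 + (nb + nc) * dbc ** 2 - nc * h ** 2)
                    / (na + nb + nc)
                )
            else:
                raise ValueError(linkage)
            dist[(min(next_id, c), max(next_id, c))] = float(new)
        clusters[next_id] = merged
        next_id += 1
    return heights, coph


def pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
    """Direct enumeration of item pairs: (both together, a-only, b-only, both apart)."""
    n11 = n10 = n01 = n00 = 0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                n11 += 1
            elif same_a:
                n10 += 1
            elif same_b:
                n01 += 1
            else:
                n00 += 1
    return n11, n10, n01, n00


def rand_from_pairs(a: np.ndarray, b: np.ndarray) -> float:
    n11, n10, n01, n00 = pair_counts(a, b)
    return (n11 + n00) / (n11 + n10 + n01 + n00)


def ari_from_pairs(a: np.ndarray, b: np.ndarray) -> float:
    """ARI via the 2x2 pair-count form 2(ad - bc) / ((a+b)(b+d) + (a+c)(c+d))."""
    pa, pb, pc, pd = pair_counts(a, b)
    denom = (pa + pb) * (pb + pd) + (pa + pc) * (pc + pd)
    if denom == 0:
        return 1.0 if pb == pc == 0 else 0.0
    return 2.0 * (pa * pd - pb * pc) / denom


def set_partitions(items: list[int]):
    """All set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def partition_to_labels(partition: list[list[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for lab, block in enumerate(partition):
        for item in block:
            labels[item] = lab
    return labels


def best_kmeans_partition(x: np.ndarray, k: int) -> tuple[float, list[tuple[int, ...]]]:
    """Exhaustive minimum within-SS over every assignment of points to k groups."""
    n = len(x)
    best_obj, best_parts = np.inf, []
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        obj = 0.0
        for g in range(k):
            members = x[[i for i in range(n) if assignment[i] == g]]
            obj += ((members - members.mean(axis=0)) ** 2).sum()
        if obj < best_obj - 1e-12:
            best_obj, best_parts = obj, [assignment]
        elif abs(obj - best_obj) <= 1e-12:
            best_parts.append(assignment)
    return best_obj, best_parts
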