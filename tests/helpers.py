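"""Independent oracles used by the test suite.

Everything here is deliberately naive (enumeration, quadratic DP,
scipy reference implementations) and independent of the package code
paths it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_force_global_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Recursive enumeration of all global alignments (memoized)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a):
            return gap * (len(b) - j)
        if j == len(b):
            return gap * (len(a) - i)
        s = match if a[i] == b[j] else mismatch
        return max(
            s + rec(i + 1, j + 1),
            gap + rec(i + 1, j),
            gap + rec(i, j + 1),
        )

    return rec(0, 0)


def levenshtein(a: str, b: str, char_match=None) -> int:
    """Plain quadratic edit distance; ``char_match(x, y)`` overrides equality."""
    if char_match is None:
        char_match = lambda x, y: x == y  # noqa: E731
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j - 1] + (0 if char_match(ca, cb) else 1),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[-1]


def iupac_primer_match(p: str, r: str) -> bool:
    return r in IUPAC.get(p, "")


def brute_force_semiglobal(query: str, target: str, char_match=None) -> int:
    """Min edit distance of the query against any target substring."""
    best = len(query)
    for i in range(len(target) + 1):
        for j in range(i, len(target) + 1):
            best = min(best, levenshtein(query, target[i:j], char_match))
    return best


def naive_partition(dist: np.ndarray, method: str, cutoff: float) -> frozenset:
    """Agglomerative partition at a cutoff via scipy (merge distance ≤ cutoff)."""
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    labels = fcluster(Z, t=cutoff, criterion="distance")
    groups: dict[int, set[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(idx)
    return frozenset(frozenset(g) for g in groups.values())


def partition_from_level(level, ids: list[str]) -> frozenset:
    """Partition (as index sets) from a ClusterLevel."""
    index = {rid: i for i, rid in enumerate(ids)}
    return frozenset(
        frozenset(index[rid] for members in cl.members.values() for rid in members)
        for cl in level.clusters
    )


def random_distinct_distance_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric matrix with all-distinct off-diagonal entries in (0, 1)."""
    m = n * (n - 1) // 2
    while True:
        w = rng.random(m)
        if len(np.unique(w)) == m:
            break
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d[iu] = w
    d[(iu[1], iu[0])] = w
    return d


def edge_stream_from_matrix(dist: np.ndarray, ids=None):
    """Build an EdgeStream directly from a distance matrix."""
    from amplikit.cluster import EdgeStream

    n = dist.shape[0]
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    edges = sorted(
        (float(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)
    )
    es = EdgeStream(ids=list(ids), n_edges=len(edges), max_weight=max(
        (w for w, _, _ in edges), default=0.0
    ))
    es._chunks.append(edges)
    return es


def expand_degenerate(primer: str):
    """All concrete expansions of a degenerate primer (tiny primers only)."""
    return (
        "".join(p) for p in itertools.product(*(IUPAC[c] for c in primer))
    )
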