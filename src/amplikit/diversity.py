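"""Alpha and beta diversity estimators over OTU abundance tables.

Implements analytic rarefaction, the Shannon index (natural log by
default), bias-corrected Chao1, abundance-corrected shared-OTU Jaccard
and Sørensen similarity, and UPGMA dendrograms of sample similarity.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .seqio import AbundanceTable, ClusterSet, clust_to_otu_matrix

__all__ = [
    "rarefaction",
    "shannon",
    "chao1",
    "chao_shared_similarity",
    "similarity_matrix",
    "upgma_dendrogram",
    "alpha_diversity_report",
    "beta_diversity_report",
]


def _counts(sample_counts: Sequence[int]) -> np.ndarray:
    c = np.asarray(sample_counts, dtype=np.int64)
    if (c < 0).any():
        raise ValueError("negative counts")
    return c[c > 0]


def rarefaction(
    sample_counts: Sequence[int], ks: Sequence[int] | None = None
) -> list[tuple[int, float]]:
    """Analytic rarefaction curve: expected OTU count per subsample size.

    E[S_k] = Σ_i [1 − C(N−N_i, k) / C(N, k)], evaluated in log space.
    ``ks`` defaults to 1..N.
    """
    c = _counts(sample_counts)
    n = int(c.sum())
    if n < 1:
        raise ValueError("empty sample")
    if ks is None:
        ks = range(1, n + 1)

    def log_choose(a: np.ndarray | int, b: int) -> np.ndarray:
        a = np.asarray(a, dtype=np.float64)
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    curve: list[tuple[int, float]] = []
    for k in ks:
        if not 1 <= k <= n:
            raise ValueError(f"subsample size {k} outside 1..{n}")
        keep = (n - c) >= k
        term = np.zeros(len(c))
        if keep.any():
            term[keep] = np.exp(log_choose(n - c[keep], k) - log_choose(n, k))
        curve.append((int(k), float(np.sum(1.0 - term))))
    return curve


def shannon(sample_counts: Sequence[int], base: float | None = None) -> float:
    """Shannon index H = −Σ p_i log p_i (natural log unless *base* given)."""
    c = _counts(sample_counts)
    n = c.sum()
    if n < 1:
        raise ValueError("empty sample")
    p = c / n
    h = float(-np.sum(p * np.log(p)))
    return h / math.log(base) if base is not None else h


def chao1(sample_counts: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form (default): S_obs + f1(f1−1)/(2(f2+1)).
    Classic form: S_obs + f1²/(2 f2), with the bias-corrected fallback
    when f2 = 0.
    """
    c = _counts(sample_counts)
    s_obs = len(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def chao_shared_similarity(
    counts_1: Sequence[int], counts_2: Sequence[int]
) -> tuple[float, float]:
    """Abundance-corrected shared-OTU (Jaccard, Sørensen) similarity.

    For paired abundances (x_i, y_i) over shared OTUs with sample sizes
    n and m::

        U = Σ x_i/n + ((m−1)/m) · f_+1/(2 f_+2) · Σ_{y_i=1} x_i/n

    and symmetrically V; U and V are capped at 1.  f_+1/f_+2 count shared
    OTUs observed exactly once/twice in the *other* sample.  When f_+2 is
    zero the denominator uses max(2·f_+2, 2).  Jaccard = UV/(U+V−UV),
    Sørensen = 2UV/(U+V); both 0 when no OTUs are shared.
    """
    x = np.asarray(counts_1, dtype=np.int64)
    y = np.asarray(counts_2, dtype=np.int64)
    if len(x) != len(y):
        raise ValueError("samples must share one OTU index")
    n = int(x.sum())
    m = int(y.sum())
    if n < 1 or m < 1:
        raise ValueError("empty sample")
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return 0.0, 0.0
    xs = x[shared]
    ys = y[shared]

    def _u(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> float:
        # a: counts in this sample, b: counts in the other sample
        f1 = int((b == 1).sum())
        f2 = int((b == 2).sum())
        u = a.sum() / na
        u += ((nb - 1) / nb) * (f1 / max(2 * f2, 2)) * (a[b == 1].sum() / na)
        return min(u, 1.0)

    u = _u(xs, ys, n, m)
    v = _u(ys, xs, m, n)
    if u == 0.0 or v == 0.0:
        return 0.0, 0.0
    jaccard = u * v / (u + v - u * v)
    sorensen = 2 * u * v / (u + v)
    return jaccard, sorensen


def similarity_matrix(
    table: AbundanceTable, index: str = "jaccard"
) -> np.ndarray:
    """Pairwise sample similarity matrix (unit diagonal)."""
    if index not in {"jaccard", "sorensen"}:
        raise ValueError(f"unknown index {index!r}")
    k = len(table.samples)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            jac, sor = chao_shared_similarity(
                table.counts[:, i], table.counts[:, j]
            )
            sim[i, j] = sim[j, i] = jac if index == "jaccard" else sor
    return sim


def upgma_dendrogram(
    similarity: np.ndarray, labels: Sequence[str]
) -> str:
    """UPGMA tree (newick, with branch lengths) on distance 1 − similarity.

    Requires at least two samples and a symmetric matrix with unit
    diagonal.  Node heights are ultrametric half-distances.
    """
    sim = np.asarray(similarity, dtype=np.float64)
    k = sim.shape[0]
    if k < 2:
        raise ValueError("UPGMA requires two or more samples")
    if sim.shape != (k, k) or len(labels) != k:
        raise ValueError("matrix/labels shape mismatch")
    if not np.allclose(sim, sim.T) or not np.allclose(np.diag(sim), 1.0):
        raise ValueError("similarity matrix must be symmetric with unit diagonal")
    dist = 1.0 - sim

    # naive UPGMA: merge closest pair, average distances weighted by size
    active = {i: (str(labels[i]), 1, 0.0) for i in range(k)}  # newick, size, height
    d = {
        (i, j): float(dist[i, j]) for i in range(k) for j in range(i + 1, k)
    }
    nxt = k
    while len(active) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, si, hi = active.pop(i)
        nj, sj, hj = active.pop(j)
        h = dij / 2.0
        newick = f"({ni}:{h - hi:.10g},{nj}:{h - hj:.10g})"
        for pair in list(d):
            if i in pair or j in pair:
                del d[pair]
        active[nxt] = (newick, si + sj, h)
        dist = _expand_distance(dist, i, j, si, sj)
        for x in active:
            if x == nxt:
                continue
            a, b = (x, nxt) if x < nxt else (nxt, x)
            d[(a, b)] = float(dist[x, nxt])
        nxt += 1
    newick, _, _ = next(iter(active.values()))
    return newick + ";"


def _expand_distance(
    dist: np.ndarray, i: int, j: int, si: int, sj: int
) -> np.ndarray:
    """Append the UPGMA-averaged row/column for the merge of i and j."""
    k = dist.shape[0]
    new = np.zeros((k + 1, k + 1))
    new[:k, :k] = dist
    merged = (si * dist[i, :] + sj * dist[j, :]) / (si + sj)
    new[k, :k] = merged
    new[:k, k] = merged
    new[k, k] = 0.0
    return new


# ---------------------------------------------------------------------------
# reports


def alpha_diversity_report(
    cs: ClusterSet, cutoffs: Sequence[float] | None = None
) -> list[dict]:
    """Shannon/Chao1/S_obs per sample at each cutoff."""
    rows = []
    for cutoff in cutoffs if cutoffs is not None else cs.cutoffs:
        table = clust_to_otu_matrix(cs, cutoff)
        for s in table.samples:
            counts = table.sample_counts(s)
            counts = counts[counts > 0]
            if len(counts) == 0:
                continue
            rows.append(
                {
                    "cutoff": cutoff,
                    "sample": s,
                    "n_seqs": int(counts.sum()),
                    "s_obs": int(len(counts)),
                    "shannon": shannon(counts),
                    "chao1": chao1(counts),
                }
            )
    return rows


def beta_diversity_report(
    cs: ClusterSet,
    out_dir: str | Path,
    cutoffs: Sequence[float] | None = None,
) -> None:
    """Similarity matrices (TSV) and UPGMA newick trees per index/cutoff."""
    if len(cs.samples) < 2:
        raise ValueError("beta diversity requires two or more samples")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cutoff in cutoffs if cutoffs is not None else cs.cutoffs:
        table = clust_to_otu_matrix(cs, cutoff)
        for index in ("jaccard", "sorensen"):
            sim = similarity_matrix(table, index)
            name = f"{index}_{cutoff:g}"
            with open(out / f"{name}.tsv", "w") as fh:
                fh.write("sample\t" + "\t".join(table.samples) + "\n")
                for s, row in zip(table.samples, sim):
                    fh.write(s + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
            with open(out / f"{name}.nwk", "w") as fh:
                fh.write(upgma_dendrogram(sim, table.samples) + "\n")
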