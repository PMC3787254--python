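"""Pairwise uncorrected distances and memory-constrained streaming
agglomerative clustering.

A *thin edge* is one pairwise sequence distance; a *thick edge* is the
collection of thin edges between two clusters.  The clustering consumes a
stream of thin edges sorted by non-decreasing weight:

* single linkage — two clusters merge at the first thin edge between them;
* complete linkage — a thick edge's weight is the largest thin edge seen
  so far, and two clusters merge once every thin edge between them has
  been seen;
* average linkage — the thick edge's weight is the running mean of the
  seen thin edges.  Because edges arrive sorted, the mean can be bounded:
  substituting the last-seen weight for unseen edges gives a lower bound,
  and substituting the largest distance observed during the distance
  computation gives an upper bound.  A pair of clusters is merged when its
  upper bound drops below the smallest lower bound of every other
  candidate pair.

If the number of retained thick edges exceeds the memory budget, the
remaining distances are scanned to fill out the thick edges between all
current clusters and clustering then resumes with exact weights.

Distances are uncorrected: mismatches over comparable (non-insert, per
the alignment mask) columns where both records have a residue.  Columns
where either record has a gap are excluded from numerator and
denominator.  Comparison is case-insensitive; two IUPAC codes match when
their base sets intersect; other characters (e.g. amino acids) match
only by equality.
"""

from __future__ import annotations

import heapq
import math
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from ._iupac import GAP_CHARS, IUPAC_SETS
from .seqio import Cluster, ClusterLevel, ClusterSet, MaskedAlignment

__all__ = [
    "pairwise_distance",
    "distance_matrix",
    "EdgeStream",
    "edge_stream",
    "cluster_stream",
    "cluster_alignment",
    "representative_sequences",
    "DEFAULT_MIN_OVERLAP",
]

DEFAULT_MIN_OVERLAP = 25


# ---------------------------------------------------------------------------
# distances

_CODE_TABLE = np.zeros(256, dtype=np.uint8)
for _c, _s in IUPAC_SETS.items():
    _bits = 0
    for _b, _bit in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
        if _b in _s:
            _bits |= _bit
    _CODE_TABLE[ord(_c)] = _bits
    _CODE_TABLE[ord(_c.lower())] = _bits
for _i in range(128):
    _ch = chr(_i)
    if _CODE_TABLE[_i] == 0 and _ch not in GAP_CHARS and _ch.isalpha():
        # non-nucleotide residue (e.g. amino acid): match by identity only
        _CODE_TABLE[_i] = 16 + (ord(_ch.upper()) - ord("A"))
# gaps and anything else stay 0 = "no residue"


def _encode(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def pairwise_distance(
    seq_a: str,
    seq_b: str,
    mask: str | None = None,
    min_overlap: int = 1,
) -> float:
    """Uncorrected distance between two aligned records.

    ``mask`` marks comparable columns (non-gap characters); when omitted
    every column is comparable.  Raises when fewer than ``min_overlap``
    columns are compared.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned records must have equal length")
    a = _encode(seq_a)
    b = _encode(seq_b)
    valid = (a != 0) & (b != 0)
    if mask is not None:
        if len(mask) != len(seq_a):
            raise ValueError("mask length does not match records")
        valid &= _CODE_TABLE[np.frombuffer(mask.encode(), dtype=np.uint8)] != 0
    compared = int(valid.sum())
    if compared < max(min_overlap, 1):
        raise ValueError(
            f"distance undefined: only {compared} compared positions "
            f"(min_overlap={min_overlap})"
        )
    both_nuc = (a < 16) & (b < 16)
    match = np.where(both_nuc, (a & b) > 0, a == b)
    matches = int((match & valid).sum())
    return (compared - matches) / compared


def distance_matrix(
    aln: MaskedAlignment, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> np.ndarray:
    """Full pairwise uncorrected distance matrix over comparable columns."""
    cols = aln.comparable_columns
    n = len(aln.ids)
    enc = np.zeros((n, len(cols)), dtype=np.uint8)
    for i, seq in enumerate(aln.seqs):
        enc[i] = _encode(seq)[cols]
    dist = np.zeros((n, n), dtype=np.float64)
    for i in range(n - 1):
        a = enc[i]
        rows = enc[i + 1 :]
        valid = (rows != 0) & (a != 0)
        compared = valid.sum(axis=1)
        bad = compared < max(min_overlap, 1)
        if bad.any():
            j = int(np.flatnonzero(bad)[0]) + i + 1
            raise ValueError(
                f"distance undefined for pair ({aln.ids[i]!r}, "
                f"{aln.ids[j]!r}): insufficient overlap"
            )
        both_nuc = (rows < 16) & (a < 16)
        match = np.where(both_nuc, (rows & a) > 0, rows == a) & valid
        d = (compared - match.sum(axis=1)) / compared
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return dist


# ---------------------------------------------------------------------------
# edge stream


@dataclass
class EdgeStream:
    """Sorted stream of thin edges.

    Iterating yields ``(weight, i, j)`` with ``i < j`` indexing ``ids``;
    edges are sorted by weight, ties ordered by (i, j).  ``max_weight``
    is the largest pairwise distance, tracked during the distance
    computation for the average-linkage upper bound.
    """

    ids: list[str]
    n_edges: int
    max_weight: float
    _chunks: list = field(default_factory=list, repr=False)

    def __iter__(self) -> Iterator[tuple[float, int, int]]:
        iters = []
        for chunk in self._chunks:
            if isinstance(chunk, list):
                iters.append(iter(chunk))
            else:
                iters.append(_iter_edge_file(chunk))
        return heapq.merge(*iters)


def _iter_edge_file(path: Path) -> Iterator[tuple[float, int, int]]:
    with open(path) as fh:
        for line in fh:
            w, i, j = line.split()
            yield (float(w), int(i), int(j))


def edge_stream(
    aln: MaskedAlignment,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    memory_budget_edges: int | None = None,
    tmp_dir: str | Path | None = None,
) -> EdgeStream:
    """All n(n−1)/2 thin edges, sorted ascending by weight.

    With ``memory_budget_edges`` set, sorted chunks of at most that many
    edges are spilled to disk and merged lazily (external sort); the
    resulting stream is identical to the in-memory sort.
    """
    if len(aln.ids) < 2:
        raise ValueError("need at least two records to build an edge stream")
    dist = distance_matrix(aln, min_overlap=min_overlap)
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = dist[iu, ju]
    order = np.lexsort((ju, iu, weights))
    stream = EdgeStream(
        ids=list(aln.ids),
        n_edges=len(weights),
        max_weight=float(weights.max()),
    )
    edges_sorted = [(float(weights[k]), int(iu[k]), int(ju[k])) for k in order]
    if memory_budget_edges is None or len(edges_sorted) <= memory_budget_edges:
        stream._chunks.append(edges_sorted)
        return stream
    tmp = (
        Path(tmp_dir)
        if tmp_dir is not None
        else Path(tempfile.mkdtemp(prefix="amplikit_edges_"))
    )
    tmp.mkdir(parents=True, exist_ok=True)
    for start in range(0, len(edges_sorted), memory_budget_edges):
        chunk = edges_sorted[start : start + memory_budget_edges]
        path = tmp / f"chunk_{start}.tsv"
        with open(path, "w") as fh:
            for w, i, j in chunk:
                fh.write(f"{w!r} {i} {j}\n")
        stream._chunks.append(path)
    return stream


# ---------------------------------------------------------------------------
# streaming clustering


class _ThickEdges:
    """Per-cluster-pair accumulators: [seen count, seen sum, seen max]."""

    def __init__(self) -> None:
        self.data: dict[tuple[int, int], list] = {}

    @staticmethod
    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def add(self, a: int, b: int, w: float) -> list:
        rec = self.data.setdefault(self.key(a, b), [0, 0.0, 0.0])
        rec[0] += 1
        rec[1] += w
        rec[2] = max(rec[2], w)
        return rec

    def get(self, a: int, b: int) -> list | None:
        return self.data.get(self.key(a, b))

    def pop(self, a: int, b: int) -> list | None:
        return self.data.pop(self.key(a, b), None)

    def __len__(self) -> int:
        return len(self.data)


class _StreamClusterer:
    def __init__(
        self,
        ids: list[str],
        method: str,
        upper_cap: float,
        debug_matrix: np.ndarray | None = None,
    ) -> None:
        n = len(ids)
        self.n = n
        self.method = method
        self.upper_cap = upper_cap
        self.debug_matrix = debug_matrix
        self.size: dict[int, int] = {i: 1 for i in range(n)}
        self.members: dict[int, list[int]] = {i: [i] for i in range(n)}
        self.find_cluster: dict[int, int] = {i: i for i in range(n)}
        self.thick = _ThickEdges()
        self.merges: list[tuple[float, int, int, int]] = []
        self.next_cid = n
        self.last_w = 0.0
        # early average-linkage merges whose exact mean is still streaming in:
        # pair key -> [seen, sum, total, merge index]
        self.pending: dict[tuple[int, int], list] = {}
        # (seq i, seq j) -> pending pair key for unseen internal edges
        self.pending_lookup: dict[tuple[int, int], tuple[int, int]] = {}

    # -- merging ----------------------------------------------------------

    def do_merge(self, ca: int, cb: int, height: float) -> int:
        new = self.next_cid
        self.next_cid += 1
        self.thick.pop(ca, cb)
        for x in list(self.size):
            if x in (ca, cb):
                continue
            ra = self.thick.pop(ca, x)
            rb = self.thick.pop(cb, x)
            if ra is None and rb is None:
                continue
            rec = [0, 0.0, 0.0]
            for r in (ra, rb):
                if r is not None:
                    rec[0] += r[0]
                    rec[1] += r[1]
                    rec[2] = max(rec[2], r[2])
            self.thick.data[self.thick.key(new, x)] = rec
        self.members[new] = self.members.pop(ca) + self.members.pop(cb)
        self.size[new] = self.size.pop(ca) + self.size.pop(cb)
        for idx in self.members[new]:
            self.find_cluster[idx] = new
        self.merges.append((height, ca, cb, new))
        return new

    def merge_complete_ready(self) -> None:
        """Merge every fully-seen thick edge, smallest max first."""
        while True:
            best = None
            for (ca, cb), rec in self.thick.data.items():
                if rec[0] == self.size[ca] * self.size[cb]:
                    cand = (rec[2], ca, cb)
                    if best is None or cand < best:
                        best = cand
            if best is None:
                return
            w, ca, cb = best
            self.do_merge(ca, cb, w)

    def _credit_internal(self, i: int, j: int, w: float) -> None:
        key = self.pending_lookup.pop((i, j) if i < j else (j, i), None)
        if key is None or key not in self.pending:
            return
        st = self.pending[key]
        st[0] += 1
        st[1] += w
        if st[0] == st[2]:
            height = st[1] / st[2]
            idx = st[3]
            h, a, b, new = self.merges[idx]
            self.merges[idx] = (height, a, b, new)
            del self.pending[key]

    def average_merge_pass(self, stream_done: bool) -> None:
        """Merge pairs whose mean is certifiably the global minimum."""
        while True:
            best = None  # (upper bound, ca, cb)
            for (ca, cb), rec in self.thick.data.items():
                total = self.size[ca] * self.size[cb]
                upper = (rec[1] + (total - rec[0]) * self.upper_cap) / total
                cand = (upper, ca, cb)
                if best is None or cand < best:
                    best = cand
            if best is None:
                return
            upper, ca, cb = best
            rec = self.thick.get(ca, cb)
            total = self.size[ca] * self.size[cb]
            complete = rec[0] == total
            exact = rec[1] / total if complete else None

            live = len(self.size)
            n_pairs = live * (live - 1) // 2
            min_other_lower = None
            if len(self.thick) < n_pairs and not stream_done:
                # at least one candidate pair has no seen edge yet; all its
                # edges weigh at least the last streamed weight
                min_other_lower = self.last_w
            for (xa, xb), r in self.thick.data.items():
                if (xa, xb) == self.thick.key(ca, cb):
                    continue
                t2 = self.size[xa] * self.size[xb]
                lower = (r[1] + (t2 - r[0]) * self.last_w) / t2
                if min_other_lower is None or lower < min_other_lower:
                    min_other_lower = lower

            if min_other_lower is None:
                ok = complete  # last pair standing needs its exact mean
            elif complete:
                ok = exact <= min_other_lower
            else:
                ok = upper < min_other_lower
            if not ok:
                return

            if complete:
                self.do_merge(ca, cb, exact)
            else:
                key = self.thick.key(ca, cb)
                state = [rec[0], rec[1], total, None]
                for x in self.members[ca]:
                    for y in self.members[cb]:
                        k = (x, y) if x < y else (y, x)
                        self.pending_lookup[k] = key
                self.do_merge(ca, cb, math.nan)
                state[3] = len(self.merges) - 1
                self.pending[key] = state

    def assert_bound_sandwich(self) -> None:
        dm = self.debug_matrix
        for (ca, cb), rec in self.thick.data.items():
            total = self.size[ca] * self.size[cb]
            lower = (rec[1] + (total - rec[0]) * self.last_w) / total
            upper = (rec[1] + (total - rec[0]) * self.upper_cap) / total
            ma, mb = self.members[ca], self.members[cb]
            exact = float(np.mean([dm[x, y] for x in ma for y in mb]))
            if not (lower <= exact + 1e-9 <= upper + 2e-9):
                raise AssertionError(
                    f"bound sandwich violated: {lower} <= {exact} <= {upper}"
                )


def cluster_stream(
    edges: EdgeStream,
    method: str = "complete",
    max_cutoff: float = 0.5,
    step: float = 0.01,
    sample_map: dict[str, str] | None = None,
    memory_budget: int | None = None,
    debug_matrix: np.ndarray | None = None,
) -> ClusterSet:
    """Cluster a sorted thin-edge stream and report stepped cutoff levels.

    ``sample_map`` maps sequence id → sample name (default: a single
    sample).  ``memory_budget`` bounds the number of live thick edges; on
    exhaustion the remaining stream is scanned to fill out the thick
    edges between the current clusters and clustering resumes with exact
    weights.  With ``debug_matrix`` (the full distance matrix) the
    average-linkage bound sandwich is asserted at every processed edge.

    Levels report the partition in effect at each cutoff: every merge
    whose linkage distance is ≤ the cutoff is applied.
    """
    if method not in {"single", "complete", "average"}:
        raise ValueError(f"unknown linkage method {method!r}")
    st = _StreamClusterer(edges.ids, method, edges.max_weight, debug_matrix)
    stream_iter = iter(edges)
    prev_w = -math.inf
    for w, i, j in stream_iter:
        if w < prev_w:
            raise ValueError("edge stream is not sorted by weight")
        prev_w = w
        st.last_w = w
        ca, cb = st.find_cluster[i], st.find_cluster[j]
        if ca == cb:
            st._credit_internal(i, j, w)
            continue
        if method == "single":
            st.do_merge(ca, cb, w)
            continue
        rec = st.thick.add(ca, cb, w)
        if method == "complete":
            if rec[0] == st.size[ca] * st.size[cb]:
                st.merge_complete_ready()
        else:
            if debug_matrix is not None:
                st.assert_bound_sandwich()
            st.average_merge_pass(stream_done=False)
        if memory_budget is not None and len(st.thick) > memory_budget:
            # memory exhausted: single-pass scan of the remaining
            # distances into thick edges, then resume with exact weights
            for w2, i2, j2 in stream_iter:
                st.last_w = w2
                ca2, cb2 = st.find_cluster[i2], st.find_cluster[j2]
                if ca2 == cb2:
                    st._credit_internal(i2, j2, w2)
                else:
                    st.thick.add(ca2, cb2, w2)
            break

    # stream exhausted: every remaining thick edge is fully seen
    if method == "complete":
        st.merge_complete_ready()
    elif method == "average":
        while len(st.size) > 1:
            best = None
            for (ca, cb), rec in st.thick.data.items():
                total = st.size[ca] * st.size[cb]
                if rec[0] != total:
                    raise AssertionError("incomplete thick edge after stream end")
                cand = (rec[1] / total, ca, cb)
                if best is None or cand < best:
                    best = cand
            if best is None:
                break
            st.do_merge(best[1], best[2], best[0])
    if st.pending:
        raise AssertionError("pending average merges left without exact height")
    for h, _, _, _ in st.merges:
        if math.isnan(h):
            raise AssertionError("merge with unresolved height")

    return _levels_from_merges(
        edges.ids, st.merges, len(edges.ids), max_cutoff, step, sample_map
    )


def cluster_alignment(
    aln: MaskedAlignment,
    method: str = "complete",
    max_cutoff: float = 0.5,
    step: float = 0.01,
    sample_map: dict[str, str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    memory_budget: int | None = None,
    memory_budget_edges: int | None = None,
) -> ClusterSet:
    """Convenience wrapper: distances + edge stream + clustering."""
    if len(aln.ids) == 1:
        stream = EdgeStream(ids=list(aln.ids), n_edges=0, max_weight=0.0)
    else:
        stream = edge_stream(
            aln, min_overlap=min_overlap, memory_budget_edges=memory_budget_edges
        )
    return cluster_stream(
        stream,
        method=method,
        max_cutoff=max_cutoff,
        step=step,
        sample_map=sample_map,
        memory_budget=memory_budget,
    )


def _levels_from_merges(
    ids: list[str],
    merges: list[tuple[float, int, int, int]],
    n: int,
    max_cutoff: float,
    step: float,
    sample_map: dict[str, str] | None,
) -> ClusterSet:
    if sample_map is None:
        sample_map = {rid: "sample" for rid in ids}
    missing = [rid for rid in ids if rid not in sample_map]
    if missing:
        raise ValueError(f"ids missing from sample mapping: {missing[:5]}")
    samples = sorted(set(sample_map.values()))
    sizes = [sum(1 for rid in ids if sample_map[rid] == s) for s in samples]
    cs = ClusterSet(samples=samples, sample_sizes=sizes)

    # map merge cluster ids back to a seed sequence index
    seed: dict[int, int] = {i: i for i in range(n)}
    for _, a, b, new in merges:
        seed[new] = seed[a]

    ordered = sorted(merges, key=lambda m: m[0])
    n_steps = int(round(max_cutoff / step))
    cutoffs = [round(k * step, 10) for k in range(n_steps + 1)]

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mi = 0
    for cutoff in cutoffs:
        while mi < len(ordered) and ordered[mi][0] <= cutoff + 1e-12:
            _, a, b, _new = ordered[mi]
            parent[find(seed[a])] = find(seed[b])
            mi += 1
        groups: dict[int, list[int]] = {}
        for idx in range(n):
            groups.setdefault(find(idx), []).append(idx)
        level = ClusterLevel(cutoff=cutoff, clusters=[])
        for cid, group in enumerate(
            sorted(groups.values(), key=lambda g: min(g))
        ):
            by_sample: dict[str, list[str]] = {}
            for idx in sorted(group):
                rid = ids[idx]
                by_sample.setdefault(sample_map[rid], []).append(rid)
            level.clusters.append(Cluster(cluster_id=cid, members=by_sample))
        cs.levels.append(level)
    return cs


# ---------------------------------------------------------------------------
# representative sequences


def representative_sequences(
    cs: ClusterSet,
    aln: MaskedAlignment,
    cutoff: float,
    min_overlap: int = 1,
) -> list[tuple[int, str, str]]:
    """Least-squares representative per cluster at the given cutoff.

    For each cluster the member minimizing the sum of squared distances
    to all other members is chosen; ties go to the lexicographically
    smallest id.  Returns (cluster id, representative id, aligned seq).
    """
    level = cs.level_at(cutoff)
    out: list[tuple[int, str, str]] = []
    for cl in level.clusters:
        member_ids = sorted(i for mids in cl.members.values() for i in mids)
        for rid in member_ids:
            if rid not in aln.ids:
                raise ValueError(f"cluster member {rid!r} missing from alignment")
        if len(member_ids) == 1:
            rid = member_ids[0]
            out.append((cl.cluster_id, rid, aln.seq_for(rid)))
            continue
        seqs = {rid: aln.seq_for(rid) for rid in member_ids}
        best_id: str | None = None
        best_ss: float | None = None
        for rid in member_ids:
            ss = 0.0
            for other in member_ids:
                if other != rid:
                    d = pairwise_distance(
                        seqs[rid],
                        seqs[other],
                        mask=aln.mask,
                        min_overlap=min_overlap,
                    )
                    ss += d * d
            if best_ss is None or ss < best_ss - 1e-15:
                best_ss = ss
                best_id = rid
        out.append((cl.cluster_id, best_id, seqs[best_id]))
    return out
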