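"""Degenerate oligonucleotide probe/primer search against target sets.

The query is aligned semiglobally (query fully consumed, free target
ends) against each target; distance is unit-cost edit distance
(substitutions and indels).  With ambiguity matching enabled, a position
matches when the IUPAC sets of the query and target characters
intersect; disabled, characters match only by identity.  One hit per
target is reported: lowest distance, then leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._iupac import is_iupac, iupac_intersect, normalize_bases, reverse_complement
from .seqio import Read

__all__ = ["ProbeHit", "probe_search"]


@dataclass
class ProbeHit:
    target_id: str
    distance: int
    start: int  # 0-based target offset of the aligned region
    end: int  # exclusive
    aligned_query: str
    aligned_target: str
    diff_mark: str  # '*' under differing columns


def _char_match(q: str, t: str, allow_ambiguity: bool) -> bool:
    if allow_ambiguity:
        return iupac_intersect(q, t)
    return q == t


def _best_hit(
    query: str, target: str, allow_ambiguity: bool
) -> tuple[int, int, int, str, str]:
    """Semiglobal alignment of query into target.

    Returns (distance, start, end, aligned_query, aligned_target) with
    the leftmost-start, then leftmost-end alignment among those of
    minimal distance.
    """
    m, n = len(query), len(target)
    INF = 10**9
    # dp[i][j]: (cost, start) aligning query[:i] to target ending at j
    prev: list[tuple[int, int]] = [(0, j) for j in range(n + 1)]
    rows = [prev]
    for i in range(1, m + 1):
        cur: list[tuple[int, int]] = [(i, 0)] * 1 + [(INF, 0)] * n
        qc = query[i - 1]
        for j in range(1, n + 1):
            sub_cost = 0 if _char_match(qc, target[j - 1], allow_ambiguity) else 1
            cand = (prev[j - 1][0] + sub_cost, prev[j - 1][1])
            up = (prev[j][0] + 1, prev[j][1])
            left = (cur[j - 1][0] + 1, cur[j - 1][1])
            cur[j] = min(cand, up, left)
        rows.append(cur)
        prev = cur
    best = (INF, 0, 0)
    for j in range(n + 1):
        cost, start = prev[j]
        if (cost, start, j) < best:
            best = (cost, start, j)
    dist, start, end = best

    # traceback for the aligned strings
    qa: list[str] = []
    ta: list[str] = []
    i, j = m, end
    while i > 0:
        cost, st = rows[i][j]
        if j > 0:
            sub_cost = (
                0 if _char_match(query[i - 1], target[j - 1], allow_ambiguity) else 1
            )
            if rows[i - 1][j - 1][0] + sub_cost == cost and rows[i - 1][j - 1][1] == st:
                i -= 1
                j -= 1
                qa.append(query[i])
                ta.append(target[j])
                continue
            if rows[i][j - 1][0] + 1 == cost and rows[i][j - 1][1] == st:
                j -= 1
                qa.append("-")
                ta.append(target[j])
                continue
        i -= 1
        qa.append(query[i])
        ta.append("-")
    qa.reverse()
    ta.reverse()
    return dist, start, end, "".join(qa), "".join(ta)


def probe_search(
    query: str,
    targets: Sequence[Read],
    max_distance: int = 0,
    allow_ambiguity: bool = True,
    target_plus_strand: bool = False,
) -> list[ProbeHit]:
    """Search the query (or, for reverse primers, its reverse complement
    against the plus strand) in every target; keep hits within
    ``max_distance`` differences.
    """
    if not query:
        raise ValueError("empty query")
    query = normalize_bases(query)
    if not is_iupac(query):
        raise ValueError(f"query contains non-IUPAC characters: {query!r}")
    if not targets:
        raise ValueError("empty target set")
    effective = reverse_complement(query) if target_plus_strand else query
    hits: list[ProbeHit] = []
    for t in targets:
        dist, start, end, qa, ta = _best_hit(
            effective, normalize_bases(t.bases), allow_ambiguity
        )
        if dist > max_distance:
            continue
        mark = "".join(
            " "
            if a != "-" and b != "-" and _char_match(a, b, allow_ambiguity)
            else "*"
            for a, b in zip(qa, ta)
        )
        hits.append(
            ProbeHit(
                target_id=t.id,
                distance=dist,
                start=start,
                end=end,
                aligned_query=qa,
                aligned_target=ta,
                diff_mark=mark,
            )
        )
    return hits
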