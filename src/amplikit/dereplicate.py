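"""Collapse exact-duplicate sequences and re-inflate results.

Identity is exact string equality after normalization (uppercase, U→T).
The first-seen id becomes the representative and keeps its own quality
scores; an id-mapping file records the duplicate groups and a
sample-mapping file records every read's sample.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .seqio import IdMapping, Read, SampleMapping
from ._iupac import normalize_bases

__all__ = ["dereplicate", "explode"]


def dereplicate(
    reads: Iterable[Read],
) -> tuple[list[Read], IdMapping, SampleMapping]:
    """Collapse identical sequence strings to one representative each.

    Returns (unique reads, IdMapping, SampleMapping).  Group order and
    representative choice follow first occurrence.  Duplicate read ids are
    a hard error.
    """
    uniques: list[Read] = []
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    pairs: list[tuple[str, str]] = []
    seen_ids: set[str] = set()
    for read in reads:
        if read.id in seen_ids:
            raise ValueError(f"duplicate read id {read.id!r} across inputs")
        seen_ids.add(read.id)
        key = normalize_bases(read.bases)
        pairs.append((read.id, read.sample or "sample"))
        if key in groups:
            groups[key].append(read.id)
        else:
            groups[key] = [read.id]
            order.append(key)
            uniques.append(
                Read(id=read.id, bases=key, quals=read.quals, sample=read.sample)
            )
    mapping = IdMapping([groups[k] for k in order])
    return uniques, mapping, SampleMapping(pairs)


def explode(
    results: dict[str, Read] | Sequence[Read],
    id_mapping: IdMapping,
    sample_mapping: SampleMapping,
) -> dict[str, list[Read]]:
    """Re-inflate per-representative results to every original id.

    ``results`` maps representative id → record (a sequence of records is
    keyed by id).  Every original id receives a copy of its
    representative's record, partitioned by sample.
    """
    if not isinstance(results, dict):
        results = {r.id: r for r in results}
    sample_of = sample_mapping.as_dict()
    missing = set(id_mapping.all_ids) - set(sample_of)
    if missing:
        raise ValueError(
            "ids missing from sample mapping: " + ", ".join(sorted(missing)[:5])
        )
    out: dict[str, list[Read]] = {}
    for group in id_mapping.groups:
        rep = group[0]
        if rep not in results:
            raise ValueError(f"no result record for representative {rep!r}")
        template = results[rep]
        for rid in group:
            sample = sample_of[rid]
            out.setdefault(sample, []).append(
                Read(
                    id=rid,
                    bases=template.bases,
                    quals=template.quals if rid == rep else None,
                    sample=sample,
                )
            )
    return out
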