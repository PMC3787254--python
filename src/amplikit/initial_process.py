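"""Demultiplexing and ordered quality filtering of amplicon reads.

Reads are sorted by 5' tag (exact match), then passed through five filters
in a fixed order: forward primer, reverse primer, uncalled bases (N),
trimmed length, and read quality (rQ).  A read that fails a filter is
recorded against that filter only; later filters are never evaluated.

Primer "differences" are unit-cost edit distance (substitutions + indels).
An IUPAC ambiguity code in the primer matches, at zero cost, any base in
its set; an N in the read matches nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._iupac import IUPAC_SETS, is_iupac, normalize_bases, reverse_complement
from .seqio import Read, TagTable, load_reads, write_fasta, write_qual

NO_TAG = "NoTag"
FILTER_ORDER = ("forward_primer", "reverse_primer", "n", "length", "rq")

__all__ = [
    "FilterConfig",
    "PrimerSet",
    "PrimerMatch",
    "ReadOutcome",
    "FilterReport",
    "rq_score",
    "match_forward_primer",
    "match_reverse_primer",
    "process_read",
    "process_run",
    "NO_TAG",
    "FILTER_ORDER",
]


@dataclass
class FilterConfig:
    max_fwd_diff: int = 2
    max_rev_diff: int = 1
    max_n: int = 0
    min_length: int = 150
    min_rq: float = 20.0
    keep_primer: bool = False

    def __post_init__(self) -> None:
        for name in ("max_fwd_diff", "max_rev_diff", "max_n", "min_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_rq < 0:
            raise ValueError("min_rq must be >= 0")


@dataclass
class PrimerSet:
    forward: list[str]
    reverse: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.forward:
            raise ValueError("at least one forward primer is required")
        self.forward = [normalize_bases(p) for p in self.forward]
        self.reverse = [normalize_bases(p) for p in self.reverse]
        for p in self.forward + self.reverse:
            if not p or not is_iupac(p):
                raise ValueError(f"invalid IUPAC primer {p!r}")


@dataclass
class PrimerMatch:
    found: bool
    start: int = -1
    end: int = -1  # exclusive
    diffs: int = -1
    primer: str | None = None


@dataclass
class ReadOutcome:
    read_id: str
    sample: str
    passed: bool
    failed_filter: str | None = None
    fwd_match: PrimerMatch | None = None
    rev_match: PrimerMatch | None = None
    trimmed: Read | None = None


@dataclass
class FilterReport:
    outcomes: list[ReadOutcome] = field(default_factory=list)
    rq_skipped: int = 0  # reads lacking quality, rq filter not evaluable

    def per_sample_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for oc in self.outcomes:
            c = out.setdefault(
                oc.sample,
                {"total": 0, "passed": 0, "no_tag": 0, **{f: 0 for f in FILTER_ORDER}},
            )
            c["total"] += 1
            if oc.passed:
                c["passed"] += 1
            elif oc.failed_filter is None:
                c["no_tag"] += 1
            else:
                c[oc.failed_filter] += 1
        return out

    def totals(self, exclude_notag: bool = True) -> dict[str, int]:
        tot = {"total": 0, "passed": 0, "no_tag": 0, **{f: 0 for f in FILTER_ORDER}}
        for sample, counts in self.per_sample_counts().items():
            if exclude_notag and sample == NO_TAG:
                continue
            for k, v in counts.items():
                tot[k] += v
        return tot


# ---------------------------------------------------------------------------
# rQ score


def rq_score(quals: Sequence[int]) -> float:
    """Read quality: −10·log10 of the mean per-base error probability."""
    if len(quals) == 0:
        raise ValueError("rq_score of an empty quality list is undefined")
    e = sum(10.0 ** (-q / 10.0) for q in quals) / len(quals)
    return -10.0 * math.log10(e)


# ---------------------------------------------------------------------------
# primer matching


def _primer_cost(pchar: str, rbase: str) -> int:
    # ambiguity code in the primer matches its set at zero cost;
    # N in the read matches nothing
    s = IUPAC_SETS[pchar]
    return 0 if rbase in s else 1


def _semiglobal_primer(
    primer: str, region: str
) -> tuple[int, int, int]:
    """Best alignment of the whole primer inside *region*.

    Both primer ends align to free region positions (leading and trailing
    region bases cost nothing).  Returns (diffs, start, end) minimizing
    differences, breaking ties by leftmost start then leftmost end.
    """
    m, n = len(primer), len(region)
    INF = 10**9
    # dp[j] = (cost, start) of best alignment of primer[:i] ending at region pos j
    prev = [(0, j) for j in range(n + 1)]  # i = 0: free leading gap
    for i in range(1, m + 1):
        cur = [(INF, 0)] * (n + 1)
        cur[0] = (prev[0][0] + 1, 0)  # deletion in region (primer base unmatched)
        pchar = primer[i - 1]
        for j in range(1, n + 1):
            sub = (prev[j - 1][0] + _primer_cost(pchar, region[j - 1]), prev[j - 1][1])
            dele = (prev[j][0] + 1, prev[j][1])  # primer base vs gap
            ins = (cur[j - 1][0] + 1, cur[j - 1][1])  # region base vs gap
            cur[j] = min(sub, dele, ins)
        prev = cur
    best = (INF, 0, 0)
    for j in range(n + 1):
        cost, start = prev[j]
        if (cost, start, j) < best:
            best = (cost, start, j)
    return best


def match_forward_primer(
    read: Read, primers: Sequence[str], max_diff: int
) -> PrimerMatch:
    """Best forward-primer match near the 5' end of the read.

    The search window spans the first ``len(primer) + max_diff`` bases.
    Best = fewest differences, then leftmost, then first-listed primer.
    """
    best: tuple[int, int, int, int] | None = None  # diffs, start, end, primer idx
    for idx, primer in enumerate(primers):
        window = read.bases[: len(primer) + max_diff]
        diffs, start, end = _semiglobal_primer(primer, window)
        if diffs > max_diff:
            continue
        key = (diffs, start, end, idx)
        if best is None or key < best:
            best = key
    if best is None:
        return PrimerMatch(found=False)
    diffs, start, end, idx = best
    return PrimerMatch(found=True, start=start, end=end, diffs=diffs, primer=primers[idx])


def _relaxed_prefix_match(
    rc_primer: str, bases: str, max_diff: int
) -> PrimerMatch | None:
    """Relaxed heuristic: a primer prefix terminating at the read's 3' end.

    Ungapped scan scored +1 per match and −6 per difference; accepted when
    the total weight is ≥ 6 and the difference count does not exceed
    ``max_diff`` (zero differences allowed when the user specifies 0).
    """
    n = len(bases)
    best: tuple[int, int, int, int] | None = None  # -weight, diffs, start tiebreak
    max_len = min(len(rc_primer), n)
    for length in range(1, max_len + 1):
        start = n - length
        seg = bases[start:]
        prefix = rc_primer[:length]
        diffs = sum(
            0 if _primer_cost(p, b) == 0 else 1 for p, b in zip(prefix, seg)
        )
        weight = (length - diffs) - 6 * diffs
        if weight < 6 or diffs > max_diff:
            continue
        key = (-weight, diffs, start, length)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    weight, diffs, start, length = -best[0], best[1], best[2], best[3]
    return PrimerMatch(found=True, start=start, end=len(bases), diffs=diffs)


def match_reverse_primer(
    read: Read, primers: Sequence[str], max_diff: int
) -> PrimerMatch:
    """Reverse-primer match near the 3' end of a forward-trimmed read.

    Primers are supplied in primer orientation and searched as reverse
    complements.  A full-primer match within ``max_diff`` differences is
    preferred; failing that, the relaxed prefix heuristic is applied.
    """
    rcs = [reverse_complement(p) for p in primers]
    best: tuple[int, int, int, int] | None = None
    for idx, rc in enumerate(rcs):
        window_len = len(rc) + max_diff
        offset = max(0, len(read.bases) - window_len)
        window = read.bases[offset:]
        diffs, start, end = _semiglobal_primer(rc, window)
        if diffs > max_diff:
            continue
        key = (diffs, offset + start, offset + end, idx)
        if best is None or key < best:
            best = key
    if best is not None:
        diffs, start, end, idx = best
        return PrimerMatch(found=True, start=start, end=end, diffs=diffs, primer=primers[idx])
    # relaxed prefix fallback
    fallback: PrimerMatch | None = None
    for idx, rc in enumerate(rcs):
        m = _relaxed_prefix_match(rc, read.bases, max_diff)
        if m is None:
            continue
        if (
            fallback is None
            or (m.diffs, m.start) < (fallback.diffs, fallback.start)
        ):
            m.primer = primers[idx]
            fallback = m
    return fallback if fallback is not None else PrimerMatch(found=False)


# ---------------------------------------------------------------------------
# per-read processing


def assign_tag(read: Read, tags: TagTable | None) -> tuple[str, str | None]:
    """Return (sample, tag) for the read, or (NoTag, None)."""
    if tags is None:
        return (read.sample or "sample", "")
    for tag, sample in tags.entries:
        if read.bases.startswith(tag):
            return sample, tag
    return NO_TAG, None


def process_read(
    read: Read,
    tags: TagTable | None,
    primers: PrimerSet,
    config: FilterConfig,
) -> ReadOutcome:
    """Demultiplex and filter one read; filters applied strictly in order."""
    sample, tag = assign_tag(read, tags)
    outcome = ReadOutcome(read_id=read.id, sample=sample, passed=False)
    if tag is None:
        return outcome

    body = Read(
        id=read.id,
        bases=read.bases[len(tag) :],
        quals=read.quals[len(tag) :] if read.quals is not None else None,
        sample=sample,
    )

    # 1. forward primer
    fwd = match_forward_primer(body, primers.forward, config.max_fwd_diff)
    outcome.fwd_match = fwd
    if not fwd.found:
        outcome.failed_filter = "forward_primer"
        return outcome
    cut5 = fwd.start if config.keep_primer else fwd.end
    body = Read(
        id=body.id,
        bases=body.bases[cut5:],
        quals=body.quals[cut5:] if body.quals is not None else None,
        sample=sample,
    )

    # 2. reverse primer (applied only when reverse primers were supplied)
    if primers.reverse:
        rev = match_reverse_primer(body, primers.reverse, config.max_rev_diff)
        outcome.rev_match = rev
        if not rev.found:
            outcome.failed_filter = "reverse_primer"
            return outcome
        cut3 = rev.end if config.keep_primer else rev.start
        body = Read(
            id=body.id,
            bases=body.bases[:cut3],
            quals=body.quals[:cut3] if body.quals is not None else None,
            sample=sample,
        )

    # 3. uncalled bases
    if body.bases.count("N") > config.max_n:
        outcome.failed_filter = "n"
        return outcome

    # 4. length (after trimming; primer portion excluded unless kept)
    if len(body.bases) < config.min_length:
        outcome.failed_filter = "length"
        return outcome

    # 5. read quality; skipped when no quality scores are present
    if body.quals is not None and len(body.quals) > 0:
        if rq_score(body.quals) < config.min_rq:
            outcome.failed_filter = "rq"
            return outcome

    outcome.passed = True
    outcome.trimmed = body
    return outcome


# ---------------------------------------------------------------------------
# whole-run processing


def process_reads(
    reads: Iterable[Read],
    tags: TagTable | None,
    primers: PrimerSet,
    config: FilterConfig,
) -> FilterReport:
    report = FilterReport()
    for read in reads:
        oc = process_read(read, tags, primers, config)
        if (
            oc.passed
            and (read.quals is None)
        ):
            report.rq_skipped += 1
        report.outcomes.append(oc)
    return report


def process_run(
    read_files: Sequence[str | Path],
    tags: TagTable | None,
    primers: PrimerSet,
    config: FilterConfig,
    out_dir: str | Path,
    qual_files: Sequence[str | Path] | None = None,
) -> FilterReport:
    """Process one or more read files and write per-sample outputs.

    Creates one subdirectory per sample (plus ``NoTag``), each holding
    trimmed sequences (``trimmed.fasta`` and ``trimmed.qual`` when
    qualities exist), a failed-read listing, a best-primer listing, and
    length/quality statistics; a run-level ``summary.txt`` records the
    per-filter counts in filter order.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    if qual_files is not None and len(qual_files) != len(read_files):
        raise ValueError("need one qual file per read file")

    all_reads: list[Read] = []
    for i, rf in enumerate(read_files):
        qp = qual_files[i] if qual_files else None
        all_reads.extend(load_reads(rf, qual_path=qp))

    report = process_reads(all_reads, tags, primers, config)

    by_sample: dict[str, list[ReadOutcome]] = {}
    for oc in report.outcomes:
        by_sample.setdefault(oc.sample, []).append(oc)

    for sample, outcomes in by_sample.items():
        sdir = out_dir / sample
        sdir.mkdir(exist_ok=True)
        passed = [oc.trimmed for oc in outcomes if oc.passed]
        write_fasta(passed, sdir / "trimmed.fasta")
        if any(r.quals is not None for r in passed):
            write_qual([r for r in passed if r.quals is not None], sdir / "trimmed.qual")
        with open(sdir / "failed_reads.txt", "w") as fh:
            fh.write("read_id\tfailed_filter\n")
            for oc in outcomes:
                if not oc.passed:
                    fh.write(f"{oc.read_id}\t{oc.failed_filter or 'no_tag'}\n")
        with open(sdir / "primer_matches.txt", "w") as fh:
            fh.write("read_id\tfwd_primer\tfwd_diffs\trev_primer\trev_diffs\n")
            for oc in outcomes:
                f = oc.fwd_match
                r = oc.rev_match
                fh.write(
                    "\t".join(
                        [
                            oc.read_id,
                            f.primer if f and f.found else "-",
                            str(f.diffs) if f and f.found else "-",
                            r.primer if r and r.found else "-",
                            str(r.diffs) if r and r.found else "-",
                        ]
                    )
                    + "\n"
                )
        with open(sdir / "stats.txt", "w") as fh:
            lengths = [len(r.bases) for r in passed]
            fh.write(f"passed reads\t{len(passed)}\n")
            if lengths:
                fh.write(f"mean length\t{sum(lengths) / len(lengths):.1f}\n")
                fh.write(f"min length\t{min(lengths)}\n")
                fh.write(f"max length\t{max(lengths)}\n")
            rqs = [rq_score(r.quals) for r in passed if r.quals]
            if rqs:
                fh.write(f"mean rQ\t{sum(rqs) / len(rqs):.2f}\n")

    with open(out_dir / "summary.txt", "w") as fh:
        fh.write("sample\ttotal\tpassed\t" + "\t".join(FILTER_ORDER) + "\n")
        for sample in sorted(by_sample):
            c = report.per_sample_counts()[sample]
            fh.write(
                sample
                + "\t"
                + "\t".join(
                    str(c[k]) for k in ("total", "passed", *FILTER_ORDER)
                )
                + "\n"
            )
        tot = report.totals()
        fh.write(
            "TOTAL(tagged)\t"
            + "\t".join(str(tot[k]) for k in ("total", "passed", *FILTER_ORDER))
            + "\n"
        )
        if report.rq_skipped:
            fh.write(
                f"# rq filter skipped for {report.rq_skipped} reads without "
                "quality scores\n"
            )
    return report
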