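"""Defined-community sequencing-error analysis.

Each read is globally aligned (Needleman–Wunsch, linear gap penalties)
against every reference sequence of the defined community; the
highest-scoring reference identifies the source organism.  Substitution
and indel errors are tabulated per alignment column with homopolymer
context, and summarized by reference, error type, and rQ bin.

Scoring: match +1, mismatch −1, gap −2 (linear).  Traceback prefers the
diagonal, then a gap in the read; indels are then slid to the 3'-most
equivalent position of their homopolymer run, which leaves the score
unchanged and makes run context well-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .initial_process import rq_score
from .seqio import Read

__all__ = [
    "Scoring",
    "PairwiseAlignment",
    "SubstitutionRecord",
    "IndelRecord",
    "ReadErrorProfile",
    "ErrorSummary",
    "global_align",
    "align_score",
    "assign_best_reference",
    "tabulate_errors",
    "profile_read",
    "summarize",
    "flag_outliers",
    "run_error_analysis",
]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass
class PairwiseAlignment:
    read_id: str
    ref_id: str
    aligned_read: str
    aligned_ref: str
    score: int
    ambiguous_ref: bool = False  # best reference tied with another

    def __post_init__(self) -> None:
        if len(self.aligned_read) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")

    @property
    def read(self) -> str:
        return self.aligned_read.replace("-", "")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace("-", "")

    def counts(self) -> tuple[int, int, int, int]:
        """(matches, substitutions, insertions, deletions)."""
        match = sub = ins = dele = 0
        for a, b in zip(self.aligned_read, self.aligned_ref):
            if b == "-":
                ins += 1
            elif a == "-":
                dele += 1
            elif a == b:
                match += 1
            else:
                sub += 1
        return match, sub, ins, dele

    def error_fraction(self) -> float:
        """(subs + ins + dels) / aligned reference length."""
        _, sub, ins, dele = self.counts()
        ref_len = len(self.ref)
        if ref_len == 0:
            raise ValueError("empty reference in alignment")
        return (sub + ins + dele) / ref_len


@dataclass
class SubstitutionRecord:
    read_id: str
    ref_id: str
    position: int  # 1-based alignment column
    expected: str
    observed: str


@dataclass
class IndelRecord:
    read_id: str
    ref_id: str
    indel_type: str  # "insertion" | "deletion"
    position: int  # 1-based alignment column
    expected_hp_len: int
    observed_hp_len: int
    base: str
    read_position: int  # 1-based, non-gap characters consumed
    ref_position: int
    qual: int | None = None  # Q of the extra base, insertions only


@dataclass
class ReadErrorProfile:
    read_id: str
    ref_id: str
    ref_bases: int  # aligned reference length
    substitutions: int
    insertions: int
    deletions: int
    rq: float | None = None
    rev_diffs: int | None = None
    ambiguous_ref: bool = False

    @property
    def errors(self) -> int:
        return self.substitutions + self.insertions + self.deletions


@dataclass
class ErrorSummary:
    n_reads: int
    reads_per_reference: dict[str, int]
    substitutions: int
    insertions: int
    deletions: int
    ref_bases: int
    error_free_reads: int
    reads_with_indels: int
    rq_bins: dict[int, tuple[int, int]] = field(default_factory=dict)
    # bin -> (errors, ref bases)

    @property
    def total_errors(self) -> int:
        return self.substitutions + self.insertions + self.deletions

    @property
    def error_rate(self) -> float:
        return self.total_errors / self.ref_bases if self.ref_bases else 0.0

    @property
    def error_free_fraction(self) -> float:
        return self.error_free_reads / self.n_reads if self.n_reads else 0.0

    @property
    def indel_read_fraction(self) -> float:
        return self.reads_with_indels / self.n_reads if self.n_reads else 0.0


# ---------------------------------------------------------------------------
# alignment

_DEFAULT = Scoring()


def _score_matrix(a: str, b: str, scoring: Scoring) -> np.ndarray:
    """Full DP matrix H with H[i, j] = best score of a[:i] vs b[:j].

    Rows are vectorized: with linear gap cost g, the within-row
    recurrence H[i,j] = max(M[j], H[i,j-1] + g) resolves to a running
    maximum of M[j] - g*j.
    """
    n, m = len(a), len(b)
    g = scoring.gap
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = g * np.arange(m + 1)
    j_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        subst = np.where(bv == av[i - 1], scoring.match, scoring.mismatch)
        M = np.empty(m + 1, dtype=np.int32)
        M[0] = H[i - 1, 0] + g  # gap in b
        np.maximum(H[i - 1, :m] + subst, H[i - 1, 1:] + g, out=M[1:])
        # H[i, j] = max over k <= j of M[k] + g*(j-k)
        np.subtract(M, g * j_idx, out=M)
        np.maximum.accumulate(M, out=M)
        H[i] = M + g * j_idx
    return H


def align_score(a: str, b: str, scoring: Scoring = _DEFAULT) -> int:
    """Optimal global alignment score (no traceback)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    return int(_score_matrix(a, b, scoring)[-1, -1])


def _slide_indels_3prime(read_aln: list[str], ref_aln: list[str]) -> None:
    """Shift every gap run to the 3'-most equivalent position, in place."""
    n = len(read_aln)
    moved = True
    while moved:
        moved = False
        for seq, other in ((read_aln, ref_aln), (ref_aln, read_aln)):
            c = 0
            while c < n - 1:
                if seq[c] == "-" and seq[c + 1] != "-" and other[c + 1] != "-":
                    # swapping keeps both ungapped sequences; score is
                    # unchanged iff the non-gap row has equal chars
                    if other[c] == other[c + 1]:
                        seq[c], seq[c + 1] = seq[c + 1], seq[c]
                        moved = True
                c += 1


def global_align(
    a: str,
    b: str,
    scoring: Scoring = _DEFAULT,
    read_id: str = "read",
    ref_id: str = "ref",
) -> PairwiseAlignment:
    """Optimal global alignment of read *a* against reference *b*."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    H = _score_matrix(a, b, scoring)
    g = scoring.gap
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0:
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            if h == H[i - 1, j - 1] + s:
                i -= 1
                j -= 1
                ra.append(a[i])
                rb.append(b[j])
                continue
        if j > 0 and h == H[i, j - 1] + g:  # gap in read
            j -= 1
            ra.append("-")
            rb.append(b[j])
            continue
        i -= 1
        ra.append(a[i])
        rb.append("-")
    ra.reverse()
    rb.reverse()
    _slide_indels_3prime(ra, rb)
    return PairwiseAlignment(
        read_id=read_id,
        ref_id=ref_id,
        aligned_read="".join(ra),
        aligned_ref="".join(rb),
        score=int(H[-1, -1]),
    )


def assign_best_reference(
    read: Read,
    references: Sequence[Read],
    scoring: Scoring = _DEFAULT,
) -> PairwiseAlignment:
    """Align the read to its highest-scoring reference.

    Ties are broken by reference input order and flagged ambiguous.
    """
    if not references:
        raise ValueError("empty reference set")
    scores = [align_score(read.bases, ref.bases, scoring) for ref in references]
    best = int(np.argmax(scores))
    ambiguous = scores.count(scores[best]) > 1
    aln = global_align(
        read.bases,
        references[best].bases,
        scoring,
        read_id=read.id,
        ref_id=references[best].id,
    )
    aln.ambiguous_ref = ambiguous
    return aln


# ---------------------------------------------------------------------------
# error tabulation


def _run_length(seq: str, pos: int, base: str) -> int:
    """Length of the run of *base* containing 1-based position *pos*.

    When seq[pos-1] != base (or pos is 0) the run ending at *pos* is
    counted instead, which may be zero.
    """
    n = len(seq)
    if 1 <= pos <= n and seq[pos - 1] == base:
        lo = pos - 1
        while lo > 0 and seq[lo - 1] == base:
            lo -= 1
        hi = pos - 1
        while hi + 1 < n and seq[hi + 1] == base:
            hi += 1
        return hi - lo + 1
    # run ending at pos
    count = 0
    k = min(pos, n)
    while k > 0 and seq[k - 1] == base:
        count += 1
        k -= 1
    return count


def tabulate_errors(
    aln: PairwiseAlignment, quals: Sequence[int] | None = None
) -> tuple[list[SubstitutionRecord], list[IndelRecord]]:
    """One record per error column of the alignment.

    Homopolymer lengths are maximal run lengths of the indel base in the
    ungapped reference (expected) and read (observed); positions are
    1-based.
    """
    subs: list[SubstitutionRecord] = []
    indels: list[IndelRecord] = []
    read_seq = aln.read
    ref_seq = aln.ref
    rpos = 0  # read chars consumed
    fpos = 0  # ref chars consumed
    for col, (rc, fc) in enumerate(zip(aln.aligned_read, aln.aligned_ref), 1):
        if rc != "-" and fc != "-":
            rpos += 1
            fpos += 1
            if rc != fc:
                subs.append(
                    SubstitutionRecord(
                        read_id=aln.read_id,
                        ref_id=aln.ref_id,
                        position=col,
                        expected=fc,
                        observed=rc,
                    )
                )
        elif fc == "-":  # insertion: extra base in the read
            rpos += 1
            indels.append(
                IndelRecord(
                    read_id=aln.read_id,
                    ref_id=aln.ref_id,
                    indel_type="insertion",
                    position=col,
                    expected_hp_len=_run_length(ref_seq, fpos, rc),
                    observed_hp_len=_run_length(read_seq, rpos, rc),
                    base=rc,
                    read_position=rpos,
                    ref_position=fpos,
                    qual=quals[rpos - 1] if quals is not None else None,
                )
            )
        else:  # deletion: reference base missing from the read
            fpos += 1
            indels.append(
                IndelRecord(
                    read_id=aln.read_id,
                    ref_id=aln.ref_id,
                    indel_type="deletion",
                    position=col,
                    expected_hp_len=_run_length(ref_seq, fpos, fc),
                    observed_hp_len=_run_length(read_seq, rpos, fc),
                    base=fc,
                    read_position=rpos,
                    ref_position=fpos,
                )
            )
    return subs, indels


def profile_read(
    aln: PairwiseAlignment,
    quals: Sequence[int] | None = None,
    rev_diffs: int | None = None,
) -> ReadErrorProfile:
    _, sub, ins, dele = aln.counts()
    return ReadErrorProfile(
        read_id=aln.read_id,
        ref_id=aln.ref_id,
        ref_bases=len(aln.ref),
        substitutions=sub,
        insertions=ins,
        deletions=dele,
        rq=rq_score(quals) if quals else None,
        rev_diffs=rev_diffs,
        ambiguous_ref=aln.ambiguous_ref,
    )


def summarize(
    profiles: Iterable[ReadErrorProfile],
    exclude_ids: set[str] | None = None,
    rev_diffs: set[int] | None = None,
    min_rq: float | None = None,
) -> ErrorSummary:
    """Summarize per-read error profiles, optionally on a subset.

    ``exclude_ids`` drops listed reads; ``rev_diffs`` keeps only reads
    whose reverse-primer difference count is in the given set; ``min_rq``
    keeps only reads at or above the rQ threshold.
    """
    per_ref: dict[str, int] = {}
    n = subs = ins = dele = bases = free = withindel = 0
    bins: dict[int, list[int]] = {}
    for p in profiles:
        if exclude_ids and p.read_id in exclude_ids:
            continue
        if rev_diffs is not None and p.rev_diffs not in rev_diffs:
            continue
        if min_rq is not None and (p.rq is None or p.rq < min_rq):
            continue
        n += 1
        per_ref[p.ref_id] = per_ref.get(p.ref_id, 0) + 1
        subs += p.substitutions
        ins += p.insertions
        dele += p.deletions
        bases += p.ref_bases
        if p.errors == 0:
            free += 1
        if p.insertions or p.deletions:
            withindel += 1
        if p.rq is not None:
            b = bins.setdefault(math.floor(p.rq), [0, 0])
            b[0] += p.errors
            b[1] += p.ref_bases
    return ErrorSummary(
        n_reads=n,
        reads_per_reference=per_ref,
        substitutions=subs,
        insertions=ins,
        deletions=dele,
        ref_bases=bases,
        error_free_reads=free,
        reads_with_indels=withindel,
        rq_bins={k: (v[0], v[1]) for k, v in sorted(bins.items())},
    )


def flag_outliers(
    alignments: Iterable[PairwiseAlignment], threshold: float = 0.10
) -> list[str]:
    """Ids of reads at or above the per-base difference threshold.

    Intended to shortlist candidates for external chimera/contaminant
    vetting.
    """
    flagged = []
    for aln in alignments:
        errors = sum(aln.counts()[1:])
        if threshold <= 0:
            if errors >= 1:
                flagged.append(aln.read_id)
        elif aln.error_fraction() >= threshold:
            flagged.append(aln.read_id)
    return flagged


# ---------------------------------------------------------------------------
# whole-run driver


def run_error_analysis(
    reads: Sequence[Read],
    references: Sequence[Read],
    scoring: Scoring = _DEFAULT,
    rev_diffs: dict[str, int] | None = None,
) -> tuple[
    list[PairwiseAlignment],
    list[SubstitutionRecord],
    list[IndelRecord],
    list[ReadErrorProfile],
]:
    """Assign, align, and tabulate errors for every read."""
    alignments: list[PairwiseAlignment] = []
    all_subs: list[SubstitutionRecord] = []
    all_indels: list[IndelRecord] = []
    profiles: list[ReadErrorProfile] = []
    for read in reads:
        aln = assign_best_reference(read, references, scoring)
        subs, indels = tabulate_errors(aln, read.quals)
        alignments.append(aln)
        all_subs.extend(subs)
        all_indels.extend(indels)
        profiles.append(
            profile_read(
                aln,
                read.quals,
                rev_diffs.get(read.id) if rev_diffs else None,
            )
        )
    return alignments, all_subs, all_indels, profiles


def write_outputs(
    out_dir: str | Path,
    alignments: Sequence[PairwiseAlignment],
    subs: Sequence[SubstitutionRecord],
    indels: Sequence[IndelRecord],
    profiles: Sequence[ReadErrorProfile],
) -> None:
    """Write the five result files: alignments, substitutions, indels,
    per-read rQ scores, and the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "alignments.txt", "w") as fh:
        for aln in alignments:
            fh.write(f">{aln.read_id} ref={aln.ref_id} score={aln.score}\n")
            fh.write(aln.aligned_read + "\n")
            fh.write(
                "".join(
                    "|" if a == b and a != "-" else " "
                    for a, b in zip(aln.aligned_read, aln.aligned_ref)
                )
                + "\n"
            )
            fh.write(aln.aligned_ref + "\n\n")
    with open(out / "substitutions.tsv", "w") as fh:
        fh.write("read_id\tref_id\tposition\texpected\tobserved\n")
        for s in subs:
            fh.write(
                f"{s.read_id}\t{s.ref_id}\t{s.position}\t{s.expected}\t"
                f"{s.observed}\n"
            )
    with open(out / "indels.tsv", "w") as fh:
        fh.write(
            "read_id\tref_id\ttype\tposition\texpected_hp_len\t"
            "observed_hp_len\tbase\tread_position\tref_position\tqual\n"
        )
        for d in indels:
            fh.write(
                f"{d.read_id}\t{d.ref_id}\t{d.indel_type}\t{d.position}\t"
                f"{d.expected_hp_len}\t{d.observed_hp_len}\t{d.base}\t"
                f"{d.read_position}\t{d.ref_position}\t"
                f"{d.qual if d.qual is not None else '-'}\n"
            )
    with open(out / "read_rq.tsv", "w") as fh:
        fh.write("read_id\trq\n")
        for p in profiles:
            if p.rq is not None:
                fh.write(f"{p.read_id}\t{p.rq:.4f}\n")
    write_summary(out / "summary.txt", summarize(profiles))


def write_summary(path: str | Path, summary: ErrorSummary) -> None:
    with open(path, "w") as fh:
        fh.write(f"reads\t{summary.n_reads}\n")
        fh.write(f"substitutions\t{summary.substitutions}\n")
        fh.write(f"insertions\t{summary.insertions}\n")
        fh.write(f"deletions\t{summary.deletions}\n")
        fh.write(f"aligned reference bases\t{summary.ref_bases}\n")
        fh.write(f"error rate per base\t{summary.error_rate:.6f}\n")
        fh.write(f"error-free reads\t{summary.error_free_reads}\n")
        fh.write(f"error-free fraction\t{summary.error_free_fraction:.4f}\n")
        fh.write(f"reads with indels\t{summary.reads_with_indels}\n")
        fh.write(f"indel read fraction\t{summary.indel_read_fraction:.4f}\n")
        fh.write("reference\treads\n")
        for ref, nr in sorted(summary.reads_per_reference.items()):
            fh.write(f"{ref}\t{nr}\n")
        if summary.rq_bins:
            fh.write("rq_bin\terrors\tref_bases\terror_rate\n")
            for b, (e, nb) in summary.rq_bins.items():
                fh.write(f"{b}\t{e}\t{nb}\t{e / nb if nb else 0.0:.6f}\n")
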