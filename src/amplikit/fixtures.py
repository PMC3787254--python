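"""Deterministic synthetic mock-community simulator.

Generates a small defined community of related genes with embedded primer
sites, then simulates tagged amplicon reads with a configurable error
model (substitutions, indels with optional homopolymer weighting, and a
positional quality model), emitting a truth ledger that maps every read
to its source gene and injected errors.  All randomness flows from a
single seed, so identical calls reproduce identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._iupac import IUPAC_SETS, normalize_bases, reverse_complement
from .seqio import Read, write_fasta, write_fastq, write_qual

__all__ = [
    "ErrorModel",
    "MockCommunity",
    "ReadTruth",
    "build_mock_community",
    "simulate_run",
    "make_chimeras",
    "write_truth_ledger",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
]

BASES = "ACGT"

# arbitrary degenerate amplification primers used by default
DEFAULT_FWD_PRIMER = "GGYTGGATHACNGCHATGTA"
DEFAULT_REV_PRIMER = "GCRTAVGTYTCNGGRTTRTA"


@dataclass
class ErrorModel:
    """Per-base error and quality model for simulated reads.

    ``hp_multiplier`` scales indel odds by ``1 + (run length − 1) × m``,
    a model choice emulating pyrosequencing homopolymer behaviour.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    hp_multiplier: float = 0.0
    mean_q: float = 30.0
    q_decay: float = 0.0
    q_noise: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.hp_multiplier < 0:
            raise ValueError("hp_multiplier must be >= 0")


@dataclass
class MockCommunity:
    genes: list[tuple[str, str, str]]  # (gene id, full sequence, organism)
    cores: list[str]  # amplicon region between the primer sites
    fwd_primer: str
    rev_primer: str
    abundances: list[float]
    tags: dict[str, str] = field(default_factory=lambda: {"mock": "ACGTCAGT"})
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.abundances) - 1.0) > 1e-9 or any(
            a <= 0 for a in self.abundances
        ):
            raise ValueError("abundances must be positive and sum to 1")
        if len(self.abundances) != len(self.genes):
            raise ValueError("one abundance per gene required")

    def references(self) -> list[Read]:
        """Reference records covering the trimmed amplicon region."""
        return [
            Read(id=gid, bases=core)
            for (gid, _, _), core in zip(self.genes, self.cores)
        ]


@dataclass
class ReadTruth:
    read_id: str
    sample: str
    gene_id: str
    n_sub: int
    n_ins: int
    n_del: int
    template_len: int
    chimera_parents: tuple[str, str] | None = None
    breakpoint: int | None = None

    @property
    def is_chimera(self) -> bool:
        return self.chimera_parents is not None


def _concrete(primer: str, rng: np.random.Generator) -> str:
    """Random concrete expansion of a degenerate primer."""
    out = []
    for c in primer:
        choices = sorted(IUPAC_SETS[c])
        out.append(choices[rng.integers(len(choices))] if len(choices) > 1 else choices[0])
    return "".join(out)


def _iupac_edit_distance(primer: str, text: str) -> int:
    """Unit-cost edit distance; primer ambiguity matches its set freely."""
    prev = list(range(len(text) + 1))
    for i, pc in enumerate(primer, 1):
        cur = [i] + [0] * len(text)
        pset = IUPAC_SETS[pc]
        for j, tc in enumerate(text, 1):
            cur[j] = min(
                prev[j - 1] + (0 if tc in pset else 1),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[-1]


def _variant_with_diffs(
    primer: str, k: int, rng: np.random.Generator
) -> str:
    """Concrete primer-site sequence at edit distance exactly *k*.

    Substitutes *k* positions to bases outside the primer's IUPAC set,
    retrying until the substitutions cannot be collapsed into fewer
    edits by an indel re-alignment.
    """
    if k == 0:
        return _concrete(primer, rng)
    if k > len(primer) // 2:
        raise ValueError(
            f"cannot place {k} differences in primer of length {len(primer)}"
        )
    mutable = [p for p in range(len(primer)) if len(IUPAC_SETS[primer[p]]) < 4]
    if len(mutable) < k:
        raise ValueError("not enough non-N primer positions to differ at")
    for _ in range(200):
        site = list(_concrete(primer, rng))
        positions = rng.choice(len(mutable), size=k, replace=False)
        for p in (mutable[i] for i in positions):
            outside = [b for b in BASES if b not in IUPAC_SETS[primer[p]]]
            site[p] = outside[int(rng.integers(len(outside)))]
        candidate = "".join(site)
        if _iupac_edit_distance(primer, candidate) == k:
            return candidate
    raise RuntimeError(f"could not realize exactly {k} primer differences")


def _mutation_fraction(divergence: float) -> float:
    """Per-gene mutation fraction q so that two independently mutated
    copies differ at ~`divergence` of positions: p = 2q(1−q) + (2/3)q²."""
    disc = 4.0 - (16.0 / 3.0) * divergence
    if disc < 0:
        raise ValueError(f"divergence {divergence} is infeasible")
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def build_mock_community(
    n_genes: int,
    length: int = 321,
    divergence: float = 0.15,
    primer_diff_profile: Sequence[int] | None = None,
    seed: int = 0,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
    abundances: Sequence[float] | None = None,
    tags: dict[str, str] | None = None,
) -> MockCommunity:
    """Generate *n_genes* related genes with embedded primer sites.

    Gene cores are produced by mutating a random ancestor so pairwise
    distances approximate ``divergence``; the genomic primer sites carry
    the per-gene difference counts of ``primer_diff_profile`` (default all
    zero).  Amplicon reads nevertheless carry the synthetic primer
    sequence: after the first amplification rounds the primer regions
    derive from the oligos, not the genome.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    profile = list(primer_diff_profile) if primer_diff_profile else [0] * n_genes
    if len(profile) != n_genes:
        raise ValueError("primer_diff_profile length must equal n_genes")
    fwd_primer = normalize_bases(fwd_primer)
    rev_primer = normalize_bases(rev_primer)
    rng = np.random.default_rng(seed)
    q = _mutation_fraction(divergence)
    if q * length < 1 and n_genes > 1:
        raise ValueError(f"divergence {divergence} infeasible for length {length}")

    ancestor = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    genes: list[tuple[str, str, str]] = []
    cores: list[str] = []
    for g in range(n_genes):
        core = list(ancestor)
        n_mut = int(round(q * length))
        pos = rng.choice(length, size=n_mut, replace=False)
        for p in pos:
            core[p] = rng.choice([b for b in BASES if b != core[p]])
        core_s = "".join(core)
        fwd_site = _variant_with_diffs(fwd_primer, profile[g], rng)
        rev_site = _variant_with_diffs(rev_primer, profile[g], rng)
        full = fwd_site + core_s + reverse_complement(rev_site)
        genes.append((f"gene_{g}", full, f"organism_{g}"))
        cores.append(core_s)

    if abundances is None:
        abundances = [1.0 / n_genes] * n_genes
    return MockCommunity(
        genes=genes,
        cores=cores,
        fwd_primer=fwd_primer,
        rev_primer=rev_primer,
        abundances=list(abundances),
        tags=tags if tags is not None else {"mock": "ACGTCAGT"},
        seed=seed,
    )


def _quals(n: int, model: ErrorModel, rng: np.random.Generator) -> list[int]:
    q = model.mean_q - model.q_decay * np.arange(n)
    if model.q_noise > 0:
        q = q + rng.normal(0.0, model.q_noise, size=n)
    return [int(v) for v in np.clip(np.rint(q), 2, 40)]


def _run_length_at(template: str, i: int) -> int:
    b = template[i]
    lo = i
    while lo > 0 and template[lo - 1] == b:
        lo -= 1
    hi = i
    while hi + 1 < len(template) and template[hi + 1] == b:
        hi += 1
    return hi - lo + 1


def _inject_errors(
    template: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, int, int, int]:
    out: list[str] = []
    n_sub = n_ins = n_del = 0
    for i, base in enumerate(template):
        mult = 1.0 + (_run_length_at(template, i) - 1) * model.hp_multiplier
        if model.del_rate and rng.random() < min(model.del_rate * mult, 0.999):
            n_del += 1
            continue
        if model.sub_rate and rng.random() < model.sub_rate:
            base = str(rng.choice([b for b in BASES if b != base]))
            n_sub += 1
        out.append(base)
        if model.ins_rate and rng.random() < min(model.ins_rate * mult, 0.999):
            # duplicated base: the typical homopolymer over-call
            out.append(template[i])
            n_ins += 1
    return "".join(out), n_sub, n_ins, n_del


def simulate_run(
    community: MockCommunity,
    n_reads: int,
    model: ErrorModel,
    read_length: int | None = None,
    seed: int = 0,
    sample: str | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Read], list[ReadTruth]]:
    """Simulate tagged amplicon reads from the community.

    Each read is ``tag + forward primer + template-with-errors +
    revcomp(reverse primer)``, truncated to ``read_length`` when given.
    The tag and primer copies are error-free (amplicons physically derive
    from the synthetic oligos).  When ``out_dir`` is given, FASTQ and
    FASTA+QUAL files and the truth ledger are written there.
    """
    rng = np.random.default_rng(seed)
    if sample is None:
        sample = next(iter(community.tags))
    tag = community.tags[sample]
    reads: list[Read] = []
    truths: list[ReadTruth] = []
    abundances = np.asarray(community.abundances)
    for k in range(n_reads):
        g = int(rng.choice(len(community.genes), p=abundances))
        gid = community.genes[g][0]
        template = community.cores[g]
        body, n_sub, n_ins, n_del = _inject_errors(template, model, rng)
        bases = (
            tag
            + _concrete(community.fwd_primer, rng)
            + body
            + reverse_complement(_concrete(community.rev_primer, rng))
        )
        if read_length is not None:
            bases = bases[:read_length]
        rid = f"{sample}_read_{k:06d}"
        quals = _quals(len(bases), model, rng)
        reads.append(Read(id=rid, bases=bases, quals=quals, sample=sample))
        truths.append(
            ReadTruth(
                read_id=rid,
                sample=sample,
                gene_id=gid,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
                template_len=len(template),
            )
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq(reads, out / f"{sample}.fastq")
        write_fasta(reads, out / f"{sample}.fasta")
        write_qual(reads, out / f"{sample}.qual")
        write_truth_ledger(truths, out / f"{sample}_truth.tsv")
        write_fasta(community.references(), out / "references.fasta")
    return reads, truths


def make_chimeras(
    community: MockCommunity,
    n: int,
    breakpoint_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    sample: str | None = None,
) -> tuple[list[Read], list[ReadTruth]]:
    """Error-free chimeric reads spliced from two distinct parent genes."""
    if n > 0 and len(community.genes) < 2:
        raise ValueError("chimeras need at least two genes")
    rng = np.random.default_rng(seed)
    if sample is None:
        sample = next(iter(community.tags))
    tag = community.tags[sample]
    lo, hi = breakpoint_range
    reads: list[Read] = []
    truths: list[ReadTruth] = []
    for k in range(n):
        a, b = rng.choice(len(community.genes), size=2, replace=False)
        core_a, core_b = community.cores[a], community.cores[b]
        bp = int(len(core_a) * rng.uniform(lo, hi))
        body = core_a[:bp] + core_b[bp:]
        bases = (
            tag
            + _concrete(community.fwd_primer, rng)
            + body
            + reverse_complement(_concrete(community.rev_primer, rng))
        )
        rid = f"{sample}_chimera_{k:06d}"
        reads.append(
            Read(
                id=rid,
                bases=bases,
                quals=[30] * len(bases),
                sample=sample,
            )
        )
        truths.append(
            ReadTruth(
                read_id=rid,
                sample=sample,
                gene_id=community.genes[a][0],
                n_sub=0,
                n_ins=0,
                n_del=0,
                template_len=len(body),
                chimera_parents=(
                    community.genes[a][0],
                    community.genes[b][0],
                ),
                breakpoint=bp,
            )
        )
    return reads, truths


def write_truth_ledger(truths: Sequence[ReadTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsample\tgene_id\tn_sub\tn_ins\tn_del\ttemplate_len\t"
            "chimera_parents\tbreakpoint\n"
        )
        for t in truths:
            parents = (
                ",".join(t.chimera_parents) if t.chimera_parents else "-"
            )
            fh.write(
                f"{t.read_id}\t{t.sample}\t{t.gene_id}\t{t.n_sub}\t{t.n_ins}"
                f"\t{t.n_del}\t{t.template_len}\t{parents}\t"
                f"{t.breakpoint if t.breakpoint is not None else '-'}\n"
            )
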