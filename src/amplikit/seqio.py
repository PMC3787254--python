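"""Readers and writers for the file formats used across the toolkit.

Formats handled here: FASTA, FASTQ (Sanger, Phred+33), QUAL, tab-delimited
tag tables, ID/sample mapping files, masked alignments carrying a
``#=GC_RF`` metadata row, the ``.clust`` multi-cutoff cluster format, and
tab-delimited OTU abundance matrices.

All readers normalize nucleotide strings to uppercase with U mapped to T.
Writers emit ``\\n`` line endings; readers tolerate ``\\r\\n``.

.clust layout
-------------
The cluster-file format stores every cutoff level in one text file::

    samples:<TAB>S1<TAB>S2
    counts:<TAB>10<TAB>5
    cutoff:<TAB>0.03<TAB>2 clusters
    0<TAB>S1<TAB>2<TAB>id1 id2
    0<TAB>S2<TAB>1<TAB>id3
    1<TAB>S1<TAB>...

The first line lists the sample names, the second the number of sequences
per sample.  Each level starts with a ``cutoff:`` header giving the
distance and the total number of clusters, followed by one line per
(cluster, sample) pair: cluster id, sample name, member count, and the
space-separated member ids.  Samples with no sequences in a cluster get no
line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO as _BioSeqIO

from ._iupac import GAP_CHARS, normalize_bases

MASK_ID = "#=GC_RF"
METADATA_PREFIX = "#=GC"

__all__ = [
    "Read",
    "TagTable",
    "MaskedAlignment",
    "IdMapping",
    "SampleMapping",
    "Cluster",
    "ClusterLevel",
    "ClusterSet",
    "AbundanceTable",
    "load_reads",
    "write_fasta",
    "write_qual",
    "write_fastq",
    "parse_tag_table",
    "load_masked_alignment",
    "merge_masked_alignments",
    "write_masked_alignment",
    "read_id_mapping",
    "write_id_mapping",
    "read_sample_mapping",
    "write_sample_mapping",
    "read_clust",
    "write_clust",
    "clust_to_otu_matrix",
    "write_otu_matrix",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Read:
    """A sequence record with optional per-base Phred qualities."""

    id: str
    bases: str
    quals: list[int] | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be nonempty")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class TagTable:
    """Ordered (tag, sample id) pairs used for demultiplexing."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tag, sample in self.entries:
            if not sample:
                raise ValueError(f"blank sample id for tag {tag!r}")
            if tag in seen:
                raise ValueError(f"duplicate tag {tag!r}")
            seen.add(tag)
        tags = sorted(seen)
        for a, b in zip(tags, tags[1:]):
            if b.startswith(a):
                raise ValueError(
                    f"tag {a!r} is a prefix of tag {b!r}; "
                    "demultiplexing would be ambiguous"
                )

    @property
    def tags(self) -> list[str]:
        return [t for t, _ in self.entries]

    def sample_for(self, tag: str) -> str:
        for t, s in self.entries:
            if t == tag:
                return s
        raise KeyError(tag)


@dataclass
class MaskedAlignment:
    """Aligned records plus a mask row marking comparable columns.

    Mask columns that are gap characters (``-`` or ``.``) are insert
    columns; everything else is a comparable (model-match) column.
    """

    ids: list[str]
    seqs: list[str]
    mask: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate record ids in alignment")
        for rid, seq in zip(self.ids, self.seqs):
            if len(seq) != len(self.mask):
                raise ValueError(
                    f"record {rid!r} length {len(seq)} != mask length "
                    f"{len(self.mask)}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def comparable_columns(self) -> np.ndarray:
        """Indices of mask columns that are comparable (non-insert)."""
        return np.array(
            [i for i, c in enumerate(self.mask) if c not in GAP_CHARS],
            dtype=np.intp,
        )

    def seq_for(self, rid: str) -> str:
        try:
            return self.seqs[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"record {rid!r} not in alignment") from None


@dataclass
class IdMapping:
    """Groups of ids of identical sequences; first id is the representative."""

    groups: list[list[str]]

    def __post_init__(self) -> None:
        flat = [i for g in self.groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("ids appear in more than one id-mapping group")

    @property
    def all_ids(self) -> list[str]:
        return [i for g in self.groups for i in g]


@dataclass
class SampleMapping:
    """(read id, sample name) pairs."""

    pairs: list[tuple[str, str]]

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)


@dataclass
class Cluster:
    cluster_id: int
    members: dict[str, list[str]]  # sample -> member ids

    def size(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass
class ClusterLevel:
    cutoff: float
    clusters: list[Cluster]


@dataclass
class ClusterSet:
    samples: list[str]
    sample_sizes: list[int]
    levels: list[ClusterLevel] = field(default_factory=list)

    def level_at(self, cutoff: float, tol: float = 1e-9) -> ClusterLevel:
        for lv in self.levels:
            if math.isclose(lv.cutoff, cutoff, abs_tol=tol):
                return lv
        avail = ", ".join(f"{lv.cutoff:g}" for lv in self.levels)
        raise KeyError(f"no level at cutoff {cutoff:g}; available: {avail}")

    @property
    def cutoffs(self) -> list[float]:
        return [lv.cutoff for lv in self.levels]


@dataclass
class AbundanceTable:
    """OTU-by-sample count matrix."""

    otu_ids: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_otus, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.otu_ids), len(self.samples)):
            raise ValueError("count matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def sample_counts(self, sample: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample)]


# ---------------------------------------------------------------------------
# reads


def _parse_qual_file(path: str | Path) -> dict[str, list[int]]:
    quals: dict[str, list[int]] = {}
    for rec in _BioSeqIO.parse(str(path), "qual"):
        if rec.id in quals:
            raise ValueError(f"duplicate id {rec.id!r} in qual file {path}")
        quals[rec.id] = [int(q) for q in rec.letter_annotations["phred_quality"]]
    return quals


def load_reads(
    path: str | Path,
    fmt: str | None = None,
    qual_path: str | Path | None = None,
    sample: str | None = None,
) -> list[Read]:
    """Load FASTA or FASTQ reads, normalizing bases (uppercase, U→T).

    ``fmt`` is ``"fasta"`` or ``"fastq"``; inferred from the file suffix
    when omitted.  A QUAL companion file may accompany FASTA input, in
    which case every FASTA record must have a quality entry of matching
    length.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {fmt!r}")

    quals = _parse_qual_file(qual_path) if qual_path is not None else None

    reads: list[Read] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), fmt):
        if rec.id in seen:
            raise ValueError(f"duplicate read id {rec.id!r} in {path}")
        seen.add(rec.id)
        q: list[int] | None = None
        if fmt == "fastq":
            q = [int(x) for x in rec.letter_annotations["phred_quality"]]
        elif quals is not None:
            if rec.id not in quals:
                raise ValueError(f"no quality entry for record {rec.id!r}")
            q = quals[rec.id]
        bases = normalize_bases(str(rec.seq))
        if q is not None and len(q) != len(bases):
            raise ValueError(
                f"record {rec.id!r}: quality length {len(q)} != "
                f"sequence length {len(bases)}"
            )
        reads.append(Read(id=rec.id, bases=bases, quals=q, sample=sample))
    return reads


def write_fasta(reads: Iterable[Read], path: str | Path, width: int = 0) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n")
            if width > 0:
                for i in range(0, len(r.bases), width):
                    fh.write(r.bases[i : i + width] + "\n")
            else:
                fh.write(r.bases + "\n")


def write_qual(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.quals is None:
                raise ValueError(f"record {r.id!r} has no quality scores")
            fh.write(f">{r.id}\n")
            fh.write(" ".join(str(q) for q in r.quals) + "\n")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.quals is None:
                raise ValueError(f"record {r.id!r} has no quality scores")
            qstr = "".join(chr(min(q, 93) + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# tag tables


def parse_tag_table(path: str | Path) -> TagTable:
    """Parse a tab-delimited (tag, sample id) file.

    Tags are normalized to uppercase so they match reads
    case-insensitively.  Duplicate tags, blank sample ids, and tags that
    are prefixes of other tags are hard errors.
    """
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            tag, sample = parts[0].strip(), parts[1].strip()
            if not sample:
                raise ValueError(f"{path}:{lineno}: blank sample id")
            entries.append((normalize_bases(tag), sample))
    return TagTable(entries)


# ---------------------------------------------------------------------------
# masked alignments


def load_masked_alignment(path: str | Path) -> MaskedAlignment:
    """Load a FASTA alignment containing a ``#=GC_RF`` mask row.

    Any record whose id starts with ``#=GC`` is treated as metadata and
    never as a sequence; the ``#=GC_RF`` row is required.
    """
    ids: list[str] = []
    seqs: list[str] = []
    mask: str | None = None
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        # Bio splits the id at whitespace; the mask id has no spaces.
        if rec.id == MASK_ID:
            if mask is not None:
                raise ValueError(f"{path}: multiple {MASK_ID} rows")
            mask = str(rec.seq)
        elif rec.id.startswith(METADATA_PREFIX):
            continue
        else:
            if rec.id in ids:
                raise ValueError(f"{path}: duplicate record id {rec.id!r}")
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
    if mask is None:
        raise ValueError(
            f"{path}: mask row {MASK_ID} is missing; it must be present "
            "in all alignment files"
        )
    return MaskedAlignment(ids=ids, seqs=seqs, mask=mask)


def merge_masked_alignments(
    alignments: Sequence[MaskedAlignment],
) -> MaskedAlignment:
    """Merge alignments produced against the same model.

    Concatenation is valid only when every alignment carries the identical
    mask; otherwise the alignments are not column-comparable.
    """
    if not alignments:
        raise ValueError("no alignments to merge")
    mask = alignments[0].mask
    for aln in alignments[1:]:
        if aln.mask != mask:
            raise ValueError("cannot merge alignments with differing masks")
    ids: list[str] = []
    seqs: list[str] = []
    for aln in alignments:
        ids.extend(aln.ids)
        seqs.extend(aln.seqs)
    return MaskedAlignment(ids=ids, seqs=seqs, mask=mask)


def write_masked_alignment(aln: MaskedAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{MASK_ID}\n{aln.mask}\n")
        for rid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# id / sample mappings


def read_id_mapping(path: str | Path) -> IdMapping:
    groups: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            ids = line.split()
            if ids:
                groups.append(ids)
    return IdMapping(groups)


def write_id_mapping(mapping: IdMapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for group in mapping.groups:
            fh.write(" ".join(group) + "\n")


def read_sample_mapping(path: str | Path) -> SampleMapping:
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id sample', got {line!r}"
                )
            pairs.append((parts[0], parts[1]))
    return SampleMapping(pairs)


def write_sample_mapping(mapping: SampleMapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, sample in mapping.pairs:
            fh.write(f"{rid} {sample}\n")


# ---------------------------------------------------------------------------
# cluster files


def write_clust(cs: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("samples:\t" + "\t".join(cs.samples) + "\n")
        fh.write("counts:\t" + "\t".join(str(n) for n in cs.sample_sizes) + "\n")
        for lv in cs.levels:
            fh.write(f"cutoff:\t{lv.cutoff!r}\t{len(lv.clusters)} clusters\n")
            for cl in lv.clusters:
                for sample in cs.samples:
                    members = cl.members.get(sample)
                    if not members:
                        continue  # samples with no sequences are not listed
                    fh.write(
                        f"{cl.cluster_id}\t{sample}\t{len(members)}\t"
                        + " ".join(members)
                        + "\n"
                    )


def read_clust(path: str | Path) -> ClusterSet:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2 or not lines[0].startswith("samples:\t"):
        raise ValueError(f"{path}:1: malformed samples header")
    samples = lines[0].split("\t")[1:]
    if not lines[1].startswith("counts:\t"):
        raise ValueError(f"{path}:2: malformed counts header")
    sizes = [int(x) for x in lines[1].split("\t")[1:]]
    if len(sizes) != len(samples):
        raise ValueError(f"{path}:2: counts do not match sample names")

    cs = ClusterSet(samples=samples, sample_sizes=sizes)
    level: ClusterLevel | None = None
    declared: int | None = None
    clusters: dict[int, Cluster] = {}

    def _close_level() -> None:
        nonlocal level
        if level is None:
            return
        level.clusters = sorted(clusters.values(), key=lambda c: c.cluster_id)
        if declared is not None and len(level.clusters) != declared:
            raise ValueError(
                f"{path}: level {level.cutoff!r} declares {declared} "
                f"clusters but lists {len(level.clusters)}"
            )
        cs.levels.append(level)

    for lineno, line in enumerate(lines[2:], 3):
        if not line.strip():
            continue
        if line.startswith("cutoff:"):
            _close_level()
            parts = line.split("\t")
            try:
                cutoff = float(parts[1])
                declared = int(parts[2].split()[0])
            except (IndexError, ValueError):
                raise ValueError(
                    f"{path}:{lineno}: malformed level header {line!r}"
                ) from None
            level = ClusterLevel(cutoff=cutoff, clusters=[])
            clusters = {}
            continue
        if level is None:
            raise ValueError(f"{path}:{lineno}: cluster line before any level")
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: malformed cluster line")
        cid = int(parts[0])
        sample = parts[1]
        if sample not in samples:
            raise ValueError(f"{path}:{lineno}: unknown sample {sample!r}")
        members = parts[3].split()
        if len(members) != int(parts[2]):
            raise ValueError(
                f"{path}:{lineno}: member count {parts[2]} does not match "
                f"{len(members)} listed ids"
            )
        cl = clusters.setdefault(cid, Cluster(cluster_id=cid, members={}))
        if sample in cl.members:
            raise ValueError(
                f"{path}:{lineno}: duplicate sample {sample!r} in cluster {cid}"
            )
        cl.members[sample] = members
    _close_level()
    return cs


# ---------------------------------------------------------------------------
# OTU matrices


def clust_to_otu_matrix(cs: ClusterSet, cutoff: float) -> AbundanceTable:
    """Convert one cutoff level of a cluster set to an OTU count matrix.

    Rows are clusters, columns samples; marginals are conserved (row sums
    equal cluster sizes, column sums equal the per-sample sequence
    counts).
    """
    level = cs.level_at(cutoff)
    counts = np.zeros((len(level.clusters), len(cs.samples)), dtype=np.int64)
    otu_ids = []
    for row, cl in enumerate(level.clusters):
        otu_ids.append(f"cluster_{cl.cluster_id}")
        for sample, members in cl.members.items():
            counts[row, cs.samples.index(sample)] += len(members)
    return AbundanceTable(otu_ids=otu_ids, samples=list(cs.samples), counts=counts)


def write_otu_matrix(table: AbundanceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu\t" + "\t".join(table.samples) + "\n")
        for rid, row in zip(table.otu_ids, table.counts):
            fh.write(rid + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def read_otu_matrix(path: str | Path) -> AbundanceTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        samples = header[1:]
        otu_ids: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 2:
                continue
            otu_ids.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(samples)), dtype=np.int64)
    return AbundanceTable(otu_ids=otu_ids, samples=samples, counts=counts)
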