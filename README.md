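# amplikit

A toolkit for functional-gene amplicon processing: tag demultiplexing with
ordered quality filtering, exact-duplicate dereplication, defined
(mock)-community sequencing-error profiling, memory-constrained streaming
OTU clustering, representative-sequence selection, diversity estimation,
degenerate probe/primer matching, and a deterministic mock-community
simulator that makes the whole pipeline testable at desk scale.

## Modules

| module                     | purpose |
|----------------------------|---------|
| `amplikit.seqio`           | FASTA/FASTQ/QUAL, tag tables, masked alignments (`#=GC_RF` row), `.clust` cluster files, OTU matrices |
| `amplikit.initial_process` | demultiplexing + the five ordered filters (forward primer, reverse primer, N, length, rQ) |
| `amplikit.dereplicate`     | collapse identical sequences; `explode` re-inflates results |
| `amplikit.community_error` | Needleman–Wunsch alignment of reads to defined-community references; substitution/indel tabulation with homopolymer context; summaries by reference, type, and rQ bin |
| `amplikit.cluster`         | pairwise uncorrected distances over comparable columns; streaming single/complete/average-linkage clustering over sorted thin edges with thick-edge bounds and a memory-exhaustion fallback; least-squares representatives |
| `amplikit.diversity`       | analytic rarefaction, Shannon, bias-corrected Chao1, abundance-corrected Jaccard/Sørensen, UPGMA dendrograms |
| `amplikit.probe_match`     | semiglobal degenerate-oligo search with bounded edit distance |
| `amplikit.fixtures`        | seeded mock-community and read simulator with truth ledgers |
| `amplikit.pipeline`        | multi-stage orchestration from an INI config with a JSON manifest |

## Command line

Each stage is a console script (and an `amplikit` subcommand):

```bash
simulate --genes 3 --reads 2000 --sub-rate 0.002 --indel-rate 0.001 --seed 42 -o sim/
initial-process --seqs run.fastq --tags tags.tsv \
    --fwd-primers GGYTGGATHACNGCHATGTA --rev-primers GCRTAVGTYTCNGGRTTRTA \
    --max-fwd-diff 2 --max-rev-diff 1 --max-ns 0 --min-length 300 --min-rq 20 -o out/
derep out/SAMPLE/trimmed.fasta -o unique.fasta --ids ids.map --samples samples.map
explode unique.fasta --ids ids.map --samples samples.map -o replicated/
community-error --reads trimmed.fasta --refs refs.fasta -o errors/
cluster --aln aligned.fasta --method complete --cutoff 0.5 --step 0.01 -o out.clust
rep-seqs --clust out.clust --aln aligned.fasta --cutoff 0.03 -o reps.fasta
amplikit clust-to-matrix --clust out.clust --cutoff 0.03 -o otu.tsv
diversity --clust out.clust -o diversity/
probe-match --query ATGCCGYR --targets targets.fasta --max-dist 2 --ambiguity
pipeline --config run.cfg -o results/
```

Alignments are consumed, not produced: cluster inputs are FASTA
alignments from an external profile aligner carrying a `#=GC_RF` mask row
that marks the comparable (non-insert) columns.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion.  The
first two (property suite, seeded parameter recovery) are self-contained.
The third reproduces published numbers from the original defined-community
sequencing runs (ENA studies PRJEB4229/PRJEB4242) and their tag/primer/
reference inputs; it fails with an explicit message when those data are
not staged under `data/defined_community/` (they cannot be downloaded in
an offline environment).

## File formats

- **`.clust`** — line 1 `samples:` + names; line 2 `counts:` + per-sample
  sizes; per cutoff a `cutoff:<TAB><distance><TAB><k> clusters` header
  followed by one line per (cluster, sample): id, sample, count,
  space-separated member ids.  Samples without members in a cluster are
  not listed.
- **OTU matrix** — TSV; header row of sample names, first column the
  cluster id, cells are member counts.
- **ID / sample mappings** — one whitespace-separated id list per line
  (first id = retained representative) / `id sample` pairs.
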