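from __future__ import annotations

import itertools

import numpy as np
import pytest

from amplikit.community_error import (
    PairwiseAlignment,
    Scoring,
    align_score,
    assign_best_reference,
    flag_outliers,
    global_align,
    profile_read,
    run_error_analysis,
    summarize,
    tabulate_errors,
)
from amplikit.fixtures import ErrorModel, build_mock_community, make_chimeras, simulate_run
from amplikit.initial_process import FilterConfig, PrimerSet, process_reads
from amplikit.seqio import Read, TagTable

from helpers import brute_force_global_score


# ---------------------------------------------------------------------------
# alignment vs exhaustive oracle


def test_identity_alignment():
    aln = global_align("ACGT", "ACGT")
    assert aln.aligned_read == aln.aligned_ref == "ACGT"
    assert aln.score == 4
    subs, indels = tabulate_errors(aln)
    assert subs == [] and indels == []


def test_single_insertion_example():
    aln = global_align("AACGT", "ACGT")
    assert aln.score == 4 - 2
    _, indels = tabulate_errors(aln)
    assert len(indels) == 1
    rec = indels[0]
    assert rec.indel_type == "insertion"
    assert rec.base == "A"
    assert rec.expected_hp_len == 1 and rec.observed_hp_len == 2


def test_deletion_homopolymer_example():
    aln = global_align("AAT", "AAAT")
    _, indels = tabulate_errors(aln)
    assert len(indels) == 1
    rec = indels[0]
    assert rec.indel_type == "deletion"
    assert rec.base == "A"
    assert rec.expected_hp_len == 3 and rec.observed_hp_len == 2


def test_scores_equal_enumeration_all_short_pairs():
    seqs = [
        "".join(p)
        for n in (1, 2, 3)
        for p in itertools.product("ACGT", repeat=n)
    ]
    for a in seqs:
        for b in seqs:
            assert align_score(a, b) == brute_force_global_score(a, b)


def test_scores_equal_enumeration_random_length_six(rng):
    for _ in range(60):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
        assert align_score(a, b) == brute_force_global_score(a, b)


def test_alignment_recovers_ungapped_strings(rng):
    for _ in range(25):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
        aln = global_align(a, b)
        assert aln.read == a and aln.ref == b
        # traceback score equals matrix score
        sc = Scoring()
        recomputed = sum(
            sc.gap
            if "-" in (x, y)
            else (sc.match if x == y else sc.mismatch)
            for x, y in zip(aln.aligned_read, aln.aligned_ref)
        )
        assert recomputed == aln.score


def test_error_conservation(rng):
    for _ in range(20):
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = "".join(rng.choice(list("ACGT"), size=28))
        aln = global_align(a, b)
        match, sub, ins, dele = aln.counts()
        assert match + sub + ins + dele == len(aln.aligned_read)
        subs, indels = tabulate_errors(aln)
        assert len(subs) == sub
        assert len(indels) == ins + dele


def test_empty_sequence_is_error():
    with pytest.raises(ValueError):
        global_align("", "ACGT")


# ---------------------------------------------------------------------------
# reference assignment


REFS = [
    Read(id="R1", bases="ACGTACGTACGTACGTACGT"),
    Read(id="R2", bases="ACGTACGTAAAAACGTACGT"),
    Read(id="R3", bases="TTTTTTTTTTTTTTTTTTTT"),
]


def test_identical_read_assigned_to_its_reference():
    read = Read(id="q", bases=REFS[1].bases)
    aln = assign_best_reference(read, REFS)
    assert aln.ref_id == "R2"
    assert aln.score == len(read.bases)
    assert not aln.ambiguous_ref


def test_closer_reference_wins():
    bases = list(REFS[0].bases)
    bases[3] = "C"  # 1 sub from R1, several from others
    read = Read(id="q", bases="".join(bases))
    aln = assign_best_reference(read, REFS)
    assert aln.ref_id == "R1"


def test_tie_broken_by_input_order_and_flagged():
    refs = [Read(id="A", bases="ACGTACGT"), Read(id="B", bases="ACGTACGT")]
    aln = assign_best_reference(Read(id="q", bases="ACGTACGT"), refs)
    assert aln.ref_id == "A"
    assert aln.ambiguous_ref


def test_empty_reference_set_is_error():
    with pytest.raises(ValueError):
        assign_best_reference(Read(id="q", bases="ACGT"), [])


def test_assignment_accuracy_on_simulated_reads():
    community = build_mock_community(3, length=300, divergence=0.12, seed=5)
    model = ErrorModel(sub_rate=0.005, ins_rate=0.002, del_rate=0.002)
    reads, truths = simulate_run(community, 80, model, seed=6)
    refs = community.references()
    trimmed = _trim(community, reads)
    truth_by_id = {t.read_id: t.gene_id for t in truths}
    for read in trimmed:
        aln = assign_best_reference(read, refs)
        assert aln.ref_id == truth_by_id[read.id]


# ---------------------------------------------------------------------------
# summaries


def _trim(community, reads):
    tags = TagTable([(community.tags["mock"], "mock")])
    primers = PrimerSet([community.fwd_primer], [community.rev_primer])
    report = process_reads(reads, tags, primers, FilterConfig(min_rq=0))
    return [oc.trimmed for oc in report.outcomes if oc.passed]


def test_zero_error_run_summary(community, clean_run):
    reads, _ = clean_run
    trimmed = _trim(community, reads)
    assert len(trimmed) == len(reads)
    _, _, _, profiles = run_error_analysis(trimmed, community.references())
    s = summarize(profiles)
    assert s.total_errors == 0
    assert s.error_rate == 0.0
    assert s.error_free_fraction == 1.0
    assert s.indel_read_fraction == 0.0


def test_exclusion_reduces_reference_counts_exactly(community, clean_run):
    reads, truths = clean_run
    trimmed = _trim(community, reads)
    _, _, _, profiles = run_error_analysis(trimmed, community.references())
    full = summarize(profiles)
    drop = {p.read_id for p in profiles[:10]}
    sub = summarize(profiles, exclude_ids=drop)
    assert sub.n_reads == full.n_reads - len(drop)
    dropped_refs = {}
    for p in profiles[:10]:
        dropped_refs[p.ref_id] = dropped_refs.get(p.ref_id, 0) + 1
    for ref, n in full.reads_per_reference.items():
        assert sub.reads_per_reference.get(ref, 0) == n - dropped_refs.get(ref, 0)


def test_rev_diff_subsetting():
    profiles = [
        profile_read(
            PairwiseAlignment("r%d" % i, "R", "ACGT", "ACGT", 4),
            rev_diffs=i % 3,
        )
        for i in range(9)
    ]
    s = summarize(profiles, rev_diffs={1, 2})
    assert s.n_reads == 6


def test_error_rate_recomputable_from_records(community):
    model = ErrorModel(sub_rate=0.01, ins_rate=0.003, del_rate=0.003)
    reads, _ = simulate_run(community, 40, model, seed=9)
    trimmed = _trim(community, reads)
    alignments, subs, indels, profiles = run_error_analysis(
        trimmed, community.references()
    )
    s = summarize(profiles)
    assert s.substitutions == len(subs)
    assert s.insertions == sum(1 for d in indels if d.indel_type == "insertion")
    assert s.deletions == sum(1 for d in indels if d.indel_type == "deletion")
    total_ref = sum(len(a.ref) for a in alignments)
    assert s.ref_bases == total_ref
    assert s.error_rate == pytest.approx((len(subs) + len(indels)) / total_ref)


# ---------------------------------------------------------------------------
# outlier flagging


def test_small_difference_not_flagged():
    ref = "A" * 321
    read = "C" * 2 + "A" * 319  # 2 diffs / 321
    aln = global_align(read, ref, read_id="q", ref_id="r")
    assert flag_outliers([aln], threshold=0.10) == []


def test_chimera_is_flagged(community):
    # near-central breakpoints keep the chimera ~half the parent
    # divergence (~7%) away from both parents
    chimeras, _ = make_chimeras(
        community, 3, breakpoint_range=(0.45, 0.55), seed=4
    )
    trimmed = _trim(community, chimeras)
    assert len(trimmed) == 3
    alignments = [
        assign_best_reference(r, community.references()) for r in trimmed
    ]
    flagged = flag_outliers(alignments, threshold=0.04)
    assert {a.read_id for a in alignments} == set(flagged)
    # non-chimeric error-free reads are never flagged
    clean = assign_best_reference(
        Read(id="ok", bases=community.cores[0]), community.references()
    )
    assert flag_outliers([clean], threshold=0.04) == []


def test_threshold_zero_flags_any_error():
    aln = global_align("ACGA", "ACGT", read_id="q")
    assert flag_outliers([aln], threshold=0.0) == ["q"]
    clean = global_align("ACGT", "ACGT", read_id="c")
    assert flag_outliers([clean], threshold=0.0) == []
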