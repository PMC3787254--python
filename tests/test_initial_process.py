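from __future__ import annotations

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from amplikit._iupac import reverse_complement
from amplikit.fixtures import ErrorModel, simulate_run
from amplikit.initial_process import (
    FILTER_ORDER,
    NO_TAG,
    FilterConfig,
    PrimerSet,
    match_forward_primer,
    match_reverse_primer,
    process_read,
    process_reads,
    process_run,
    rq_score,
)
from amplikit.seqio import Read, TagTable

from helpers import iupac_primer_match, levenshtein

FWD = "GGYTGGATHACNGCHATGTA"
REV = "GCRTAVGTYTCNGGRTTRTA"


def _primer_edit_distance(primer: str, text: str) -> int:
    return levenshtein(primer, text, char_match=iupac_primer_match)


# ---------------------------------------------------------------------------
# rQ


def test_rq_uniform_q20_is_exactly_20():
    for n in (1, 5, 100):
        assert rq_score([20] * n) == pytest.approx(20.0, abs=1e-12)


def test_rq_worked_example():
    # E = (0.1 + 0.01)/2 = 0.055
    assert rq_score([10, 20]) == pytest.approx(-10 * math.log10(0.055), abs=1e-9)
    assert rq_score([10, 20]) == pytest.approx(12.5964, abs=1e-4)


def test_rq_monotone_in_any_single_base():
    quals = [17, 23, 30, 12]
    base = rq_score(quals)
    for i in range(len(quals)):
        bumped = list(quals)
        bumped[i] += 1
        assert rq_score(bumped) > base


def test_rq_empty_is_error():
    with pytest.raises(ValueError):
        rq_score([])


# ---------------------------------------------------------------------------
# forward primer


def test_exact_primer_at_offset_zero():
    read = Read(id="r", bases="GGCTGGATAACAGCAATGTA" + "ACGT" * 20)
    m = match_forward_primer(read, [FWD], 2)
    assert m.found and m.start == 0 and m.diffs == 0
    assert m.end == len(FWD)


def test_ambiguity_codes_match_at_zero_cost():
    read = Read(id="r", bases="GGAAAA" + "C" * 30)
    m = match_forward_primer(read, ["GGHAAR"], 2)
    assert m.found and m.diffs == 0


def test_three_substitutions_exceed_max_diff_two():
    primer = "GGCTGGATAACAGCAATGTA"
    bad = "TT" + primer[2:-1] + "G"  # 3 substitutions
    assert _primer_edit_distance(primer, bad) == 3
    read = Read(id="r", bases=bad + "A" * 50)
    m = match_forward_primer(read, [primer], 2)
    assert not m.found


def test_forward_match_agrees_with_edit_distance_oracle(rng):
    primer = "GGYTGGAT"
    for _ in range(30):
        prefix = "".join(rng.choice(list("ACGT"), size=len(primer)))
        read = Read(id="r", bases=prefix + "ACGTACGTAC")
        m = match_forward_primer(read, [primer], max_diff=3)
        window = read.bases[: len(primer) + 3]
        oracle = min(
            _primer_edit_distance(primer, window[i:j])
            for i in range(len(window) + 1)
            for j in range(i, len(window) + 1)
        )
        if oracle <= 3:
            assert m.found and m.diffs == oracle
        else:
            assert not m.found


# ---------------------------------------------------------------------------
# reverse primer (relaxed prefix heuristic)

_CONCRETE = str.maketrans("RYSWKMBDHVN", "ACCAGACAAAA")


def _concrete(s: str) -> str:
    """One concrete expansion of a degenerate sequence."""
    return s.translate(_CONCRETE)


def test_exact_six_base_prefix_weight_six_accepted():
    rc = _concrete(reverse_complement(REV))
    read = Read(id="r", bases="G" * 60 + rc[:6])
    m = match_reverse_primer(read, [REV], 1)
    assert m.found and m.start == 60


def test_twelve_base_prefix_one_diff_weight_five_rejected():
    rc = _concrete(reverse_complement(REV))
    prefix = list(rc[:12])
    # corrupt one non-degenerate position to a base outside its set
    prefix[1] = "A" if prefix[1] != "A" else "C"
    read = Read(id="r", bases="G" * 60 + "".join(prefix))
    m = match_reverse_primer(read, [REV], 1)
    assert not m.found  # weight 11 - 6 = 5 < 6


def test_thirteen_base_prefix_one_diff_weight_six_accepted():
    rc = _concrete(reverse_complement(REV))
    prefix = list(rc[:13])
    prefix[1] = "A" if prefix[1] != "A" else "C"
    read = Read(id="r", bases="G" * 60 + "".join(prefix))
    m = match_reverse_primer(read, [REV], 1)
    assert m.found and m.diffs == 1  # weight 12 - 6 = 6


def test_zero_differences_allowed_when_user_says_zero():
    rc = _concrete(reverse_complement(REV))
    prefix = list(rc[:13])
    prefix[1] = "A" if prefix[1] != "A" else "C"
    read = Read(id="r", bases="G" * 60 + "".join(prefix))
    assert not match_reverse_primer(read, [REV], 0).found
    clean = Read(id="r", bases="G" * 60 + rc[:13])
    assert match_reverse_primer(clean, [REV], 0).found


def test_full_reverse_primer_match_preferred():
    rc = _concrete(reverse_complement(REV))
    read = Read(id="r", bases="G" * 60 + rc)
    m = match_reverse_primer(read, [REV], 1)
    assert m.found and m.start == 60 and m.end == 60 + len(rc) and m.diffs == 0


# ---------------------------------------------------------------------------
# per-read processing


def _make_read(tag: str, insert: str, quals_value: int = 30) -> Read:
    bases = tag + "GGCTGGATAACAGCAATGTA" + insert + reverse_complement(
        "GCATACGTCTCAGGATTATA"
    )
    return Read(id="r1", bases=bases, quals=[quals_value] * len(bases))


TAGS = TagTable([("ACGTACGT", "S1"), ("TGCATGCA", "S2")])
PRIMERS = PrimerSet(forward=[FWD], reverse=[REV])


def test_perfect_read_passes_and_trims_to_insert(rng):
    insert = "".join(rng.choice(list("ACGT"), size=300))
    read = _make_read("ACGTACGT", insert)
    oc = process_read(read, TAGS, PRIMERS, FilterConfig())
    assert oc.sample == "S1"
    assert oc.passed
    assert oc.trimmed.bases == insert


def test_unknown_tag_goes_to_notag(rng):
    read = _make_read("GGGGCCCC", "A" * 300)
    oc = process_read(read, TAGS, PRIMERS, FilterConfig())
    assert oc.sample == NO_TAG and not oc.passed


def test_n_filter_short_circuits_before_length(rng):
    insert = "N" + "A" * 10  # too short AND contains N
    read = _make_read("ACGTACGT", insert)
    oc = process_read(read, TAGS, PRIMERS, FilterConfig(max_n=0))
    assert oc.failed_filter == "n"


def test_rq_failure_uses_rq_oracle(rng):
    insert = "".join(rng.choice(list("ACGT"), size=300))
    read = _make_read("ACGTACGT", insert, quals_value=19)
    assert rq_score(read.quals) < 20
    oc = process_read(read, TAGS, PRIMERS, FilterConfig())
    assert oc.failed_filter == "rq"


def test_filter_failure_names_exactly_first_failed():
    # fails length (after trimming) but rq would also fail
    read = _make_read("ACGTACGT", "A" * 20, quals_value=5)
    oc = process_read(read, TAGS, PRIMERS, FilterConfig())
    assert oc.failed_filter == "length"


def test_keep_primer_length_relation(rng):
    insert = "".join(rng.choice(list("ACGT"), size=300))
    read = _make_read("ACGTACGT", insert)
    kept = process_read(read, TAGS, PRIMERS, FilterConfig(keep_primer=True))
    trimmed = process_read(read, TAGS, PRIMERS, FilterConfig())
    assert len(kept.trimmed.bases) == len(trimmed.trimmed.bases) + len(FWD) + len(REV)


def test_rq_filter_skipped_without_quality(rng):
    insert = "".join(rng.choice(list("ACGT"), size=300))
    read = _make_read("ACGTACGT", insert)
    read = Read(id=read.id, bases=read.bases, quals=None)
    oc = process_read(read, TAGS, PRIMERS, FilterConfig(min_rq=40))
    assert oc.passed


# ---------------------------------------------------------------------------
# run level


def _simulated_batch(community, n=60, seed=3):
    reads, truths = simulate_run(community, n, ErrorModel(), seed=seed)
    return reads, truths


def test_counts_partition_matched_reads(community, tmp_path):
    reads, _ = _simulated_batch(community)
    tags = TagTable([(community.tags["mock"], "mock")])
    primers = PrimerSet([community.fwd_primer], [community.rev_primer])
    report = process_run(
        _write_fastq(tmp_path, reads), tags, primers, FilterConfig(), tmp_path / "out"
    )
    tot = report.totals()
    assert tot["total"] == tot["passed"] + sum(tot[f] for f in FILTER_ORDER)


def test_zero_error_simulation_passes_100_percent(community, clean_run):
    reads, _ = clean_run
    tags = TagTable([(community.tags["mock"], "mock")])
    primers = PrimerSet([community.fwd_primer], [community.rev_primer])
    report = process_reads(reads, tags, primers, FilterConfig())
    tot = report.totals()
    assert tot["passed"] == tot["total"] == len(reads)


def test_demultiplexing_order_independent(community):
    reads, _ = _simulated_batch(community)
    tags = TagTable([(community.tags["mock"], "mock")])
    primers = PrimerSet([community.fwd_primer], [community.rev_primer])
    a = process_reads(reads, tags, primers, FilterConfig())
    shuffled = list(reads)
    random.Random(5).shuffle(shuffled)
    b = process_reads(shuffled, tags, primers, FilterConfig())
    by_id_a = {oc.read_id: (oc.sample, oc.passed, oc.failed_filter) for oc in a.outcomes}
    by_id_b = {oc.read_id: (oc.sample, oc.passed, oc.failed_filter) for oc in b.outcomes}
    assert by_id_a == by_id_b


def test_all_unknown_tags_land_in_notag(community, tmp_path):
    reads, _ = _simulated_batch(community, n=20)
    tags = TagTable([("GGGGGGGG", "other")])
    primers = PrimerSet([community.fwd_primer], [community.rev_primer])
    report = process_run(
        _write_fastq(tmp_path, reads), tags, primers, FilterConfig(), tmp_path / "out2"
    )
    counts = report.per_sample_counts()
    assert set(counts) == {NO_TAG}
    assert report.totals()["total"] == 0  # tagged total excludes NoTag
    assert (tmp_path / "out2" / NO_TAG).is_dir()


def _write_fastq(tmp_path, reads):
    from amplikit.seqio import write_fastq

    p = tmp_path / "reads.fastq"
    write_fastq(reads, p)
    return [p]


@given(st.lists(st.integers(min_value=0, max_value=45), min_size=1, max_size=50))
def test_rq_bounded_by_min_and_max_q(quals):
    rq = rq_score(quals)
    assert min(quals) - 1e-9 <= rq <= max(quals) + 1e-9
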