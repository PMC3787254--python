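from __future__ import annotations

import numpy as np
import pytest

from amplikit.cluster import (
    EdgeStream,
    cluster_alignment,
    cluster_stream,
    distance_matrix,
    edge_stream,
    pairwise_distance,
    representative_sequences,
)
from amplikit.seqio import MaskedAlignment

from helpers import (
    edge_stream_from_matrix,
    naive_partition,
    partition_from_level,
    random_distinct_distance_matrix,
)


# ---------------------------------------------------------------------------
# distances


def test_identical_records_distance_zero():
    assert pairwise_distance("ACGT", "ACGT") == 0.0


def test_one_mismatch_over_four():
    assert pairwise_distance("ACGT", "ACGA") == 0.25


def test_gap_column_excluded():
    assert pairwise_distance("AC-T", "ACGT") == 0.0


def test_mask_excludes_insert_columns():
    # column 2 is an insert column; the mismatch there is not counted
    assert pairwise_distance("ACGT", "ACTT", mask="xx.x") == 0.0


def test_ambiguity_matches_when_sets_intersect():
    assert pairwise_distance("ACGR", "ACGA") == 0.0  # R = {A,G}
    assert pairwise_distance("ACGR", "ACGC") == 0.25


def test_case_insensitive():
    assert pairwise_distance("acgt", "ACGT") == 0.0


def test_min_overlap_guard():
    with pytest.raises(ValueError, match="undefined"):
        pairwise_distance("A---", "-CGT")


def test_protein_residues_match_by_identity():
    assert pairwise_distance("MKL", "MKL") == 0.0
    assert pairwise_distance("MKL", "MKI") == pytest.approx(1 / 3)


# ---------------------------------------------------------------------------
# edge stream


def _random_alignment(rng, n=50, length=60) -> MaskedAlignment:
    seqs = [
        "".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)
    ]
    return MaskedAlignment(
        ids=[f"s{i}" for i in range(n)], seqs=seqs, mask="x" * length
    )


def test_three_records_three_sorted_edges():
    aln = MaskedAlignment(
        ids=["a", "b", "c"],
        seqs=["AAAA", "AAAT", "TTTT"],
        mask="xxxx",
    )
    stream = edge_stream(aln, min_overlap=1)
    edges = list(stream)
    assert len(edges) == 3
    weights = [w for w, _, _ in edges]
    assert weights == sorted(weights)


def test_stream_matches_matrix_multiset(rng):
    aln = _random_alignment(rng)
    dist = distance_matrix(aln, min_overlap=1)
    stream = edge_stream(aln, min_overlap=1)
    weights = [w for w, _, _ in stream]
    iu = np.triu_indices(len(aln.ids), k=1)
    assert np.allclose(sorted(weights), np.sort(dist[iu]))


def test_tiny_memory_budget_yields_identical_stream(rng, tmp_path):
    aln = _random_alignment(rng, n=15)
    full = list(edge_stream(aln, min_overlap=1))
    spilled = list(
        edge_stream(aln, min_overlap=1, memory_budget_edges=1, tmp_dir=tmp_path)
    )
    assert spilled == full


def test_unsorted_stream_detected():
    es = EdgeStream(ids=["a", "b", "c"], n_edges=3, max_weight=0.9)
    es._chunks.append([(0.5, 0, 1), (0.1, 0, 2), (0.9, 1, 2)])
    with pytest.raises(ValueError, match="sorted"):
        cluster_stream(es, method="single")


# ---------------------------------------------------------------------------
# clustering vs naive oracle


def test_worked_example_complete_linkage():
    d = np.array(
        [[0.0, 0.10, 0.20], [0.10, 0.0, 0.30], [0.20, 0.30, 0.0]]
    )
    cs = cluster_stream(edge_stream_from_matrix(d), method="complete", step=0.01)
    ids = ["s0", "s1", "s2"]
    assert partition_from_level(cs.level_at(0.09), ids) == frozenset(
        {frozenset({0}), frozenset({1}), frozenset({2})}
    )
    for cutoff in (0.10, 0.29):
        assert partition_from_level(cs.level_at(cutoff), ids) == frozenset(
            {frozenset({0, 1}), frozenset({2})}
        )
    assert partition_from_level(cs.level_at(0.30), ids) == frozenset(
        {frozenset({0, 1, 2})}
    )


def test_worked_example_average_linkage():
    d = np.array(
        [[0.0, 0.10, 0.20], [0.10, 0.0, 0.30], [0.20, 0.30, 0.0]]
    )
    cs = cluster_stream(edge_stream_from_matrix(d), method="average", step=0.01)
    ids = ["s0", "s1", "s2"]
    assert partition_from_level(cs.level_at(0.10), ids) == frozenset(
        {frozenset({0, 1}), frozenset({2})}
    )
    # final merge at mean(0.20, 0.30) = 0.25
    assert partition_from_level(cs.level_at(0.24), ids) == frozenset(
        {frozenset({0, 1}), frozenset({2})}
    )
    assert partition_from_level(cs.level_at(0.25), ids) == frozenset(
        {frozenset({0, 1, 2})}
    )


@pytest.mark.parametrize("method", ["single", "complete", "average"])
@pytest.mark.parametrize("n", [2, 3, 5, 8, 13, 21, 50])
def test_matches_naive_agglomerative_oracle(method, n, rng):
    d = random_distinct_distance_matrix(n, rng)
    cs = cluster_stream(
        edge_stream_from_matrix(d), method=method, max_cutoff=1.0, step=0.05
    )
    ids = [f"s{i}" for i in range(n)]
    for level in cs.levels:
        expected = naive_partition(d, method, level.cutoff + 1e-12)
        assert partition_from_level(level, ids) == expected, (
            f"{method} n={n} cutoff={level.cutoff}"
        )


def test_average_bound_sandwich_asserted(rng):
    d = random_distinct_distance_matrix(20, rng)
    # debug mode raises if lower <= exact mean <= upper ever fails
    cluster_stream(
        edge_stream_from_matrix(d), method="average", debug_matrix=d
    )


@pytest.mark.parametrize("method", ["single", "complete", "average"])
def test_memory_budget_invariance(method, rng):
    d = random_distinct_distance_matrix(18, rng)
    results = []
    for budget in (None, 1000, 5, 1):
        cs = cluster_stream(
            edge_stream_from_matrix(d), method=method,
            max_cutoff=1.0, step=0.1, memory_budget=budget,
        )
        results.append(cs)
    for cs in results[1:]:
        assert cs == results[0]


def test_hierarchy_coarsening(rng):
    d = random_distinct_distance_matrix(25, rng)
    cs = cluster_stream(
        edge_stream_from_matrix(d), method="complete", max_cutoff=1.0, step=0.02
    )
    ids = [f"s{i}" for i in range(25)]
    prev = None
    for level in cs.levels:
        part = partition_from_level(level, ids)
        if prev is not None:
            assert len(part) <= len(prev)
            for group in prev:
                assert any(group <= g for g in part)
        prev = part


def test_single_sequence_one_cluster_every_level():
    es = EdgeStream(ids=["only"], n_edges=0, max_weight=0.0)
    cs = cluster_stream(es, method="complete", max_cutoff=0.1, step=0.05)
    assert len(cs.levels) == 3
    for level in cs.levels:
        assert len(level.clusters) == 1
        assert level.clusters[0].members == {"sample": ["only"]}


def test_sample_map_splits_counts():
    d = np.array([[0.0, 0.4], [0.4, 0.0]])
    cs = cluster_stream(
        edge_stream_from_matrix(d, ids=["a", "b"]),
        method="complete",
        sample_map={"a": "S1", "b": "S2"},
    )
    assert cs.samples == ["S1", "S2"]
    assert cs.sample_sizes == [1, 1]
    level = cs.level_at(0.4)
    assert len(level.clusters) == 1
    assert level.clusters[0].members == {"S1": ["a"], "S2": ["b"]}


def test_cluster_counts_non_increasing_with_cutoff(rng):
    aln = _random_alignment(rng, n=20, length=80)
    cs = cluster_alignment(aln, method="average", max_cutoff=0.8, step=0.05,
                           min_overlap=1)
    counts = [len(lv.clusters) for lv in cs.levels]
    assert counts == sorted(counts, reverse=True)
    # every level partitions all sequences exactly once
    for lv in cs.levels:
        members = [
            rid for cl in lv.clusters for ms in cl.members.values() for rid in ms
        ]
        assert sorted(members) == sorted(aln.ids)


# ---------------------------------------------------------------------------
# representatives


def _aln(ids_seqs):
    ids = [i for i, _ in ids_seqs]
    seqs = [s for _, s in ids_seqs]
    return MaskedAlignment(ids=ids, seqs=seqs, mask="x" * len(seqs[0]))


def test_singleton_cluster_represents_itself():
    aln = _aln([("a", "ACGT")])
    cs = cluster_stream(
        EdgeStream(ids=["a"], n_edges=0, max_weight=0.0), max_cutoff=0.03
    )
    reps = representative_sequences(cs, aln, 0.03)
    assert reps == [(0, "a", "ACGT")]


def test_least_squares_representative():
    # b is the centroid: sum of squared distances strictly smallest
    aln = _aln(
        [
            ("a", "AAAAAAAACC"),
            ("b", "AAAAAAAAAC"),
            ("c", "AAAAAAAAAA"),
        ]
    )
    cs = cluster_alignment(aln, max_cutoff=0.5, step=0.1, min_overlap=1)
    level_cut = 0.5
    # brute-force the sum of squared distances
    def ssq(x):
        return sum(
            pairwise_distance(aln.seq_for(x), aln.seq_for(o)) ** 2
            for o in aln.ids
            if o != x
        )

    best = min(aln.ids, key=ssq)
    assert best == "b"
    reps = representative_sequences(cs, aln, level_cut)
    assert reps[0][1] == "b"


def test_representative_tie_breaks_lexicographically():
    aln = _aln([("z", "AAAA"), ("a", "AATT")])  # symmetric pair
    cs = cluster_alignment(aln, max_cutoff=0.5, step=0.5, min_overlap=1)
    reps = representative_sequences(cs, aln, 0.5)
    assert reps[0][1] == "a"


def test_missing_member_is_error():
    aln = _aln([("a", "ACGT")])
    cs = cluster_stream(
        EdgeStream(ids=["a", "b"], n_edges=1, max_weight=0.1,
                   _chunks=[[(0.1, 0, 1)]]),
        max_cutoff=0.03,
    )
    with pytest.raises(ValueError, match="b"):
        representative_sequences(cs, aln, 0.0)
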