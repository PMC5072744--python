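"""Authenticity criteria, deduplication, 250-bp clustering and junction
classification."""

import numpy as np
import pytest

from retromap.align import Alignment
from retromap.formats import GenomeRef
from retromap.readprep import ANCHOR_3, PreppedRead
from retromap.synthetic import synthetic_provirus
from retromap.tradis import (
    INTEGRASE,
    UNRESOLVED,
    ConsistencyError,
    FilterParams,
    JunctionCall,
    call_sites,
    classify_junction,
    cluster_positions,
    dedup_and_unique,
    library_summary,
)


def _prepped(read_id="r1", host="GATTACA" * 10, complete=True, splink=False, end=3):
    return PreppedRead(
        id=read_id,
        host_sequence=host,
        evidence="merged",
        ltr_end=end,
        anchor_found=True,
        anchor_complete=complete,
        anchor_match_len=37 if complete else 30,
        splinkerette_immediately_after_anchor=splink,
    )


def _aln(read_id="r1", ref="chr1", start=5000, span=60, strand="+", qstart=0,
         matched=None, mism=0, mapq=60, coopt=1):
    matched = span - mism if matched is None else matched
    return Alignment(
        read_id=read_id, reference=ref, start=start, end=start + span,
        strand=strand, qstart=qstart, qend=qstart + span, query_length=qstart + span,
        matched_bp=matched, mismatches=mism, mapq=mapq, n_cooptimal=coopt,
    )


@pytest.fixture(scope="module")
def genome():
    return GenomeRef(sequences={"chr1": "A" * 20_000})


@pytest.fixture(scope="module")
def pv():
    return synthetic_provirus(seed=7)


class TestCallSites:
    def test_passing_read_yields_one_call_at_flank_boundary(self, genome, pv):
        params = FilterParams()
        calls, tally = call_sites(
            [_prepped()], {"r1": [_aln()]}, params, genome, pv
        )
        assert tally["passed"] == 1
        (call,) = calls
        assert (call.chromosome, call.position, call.strand) == ("chr1", 5000, "+")
        assert call.junction_class == INTEGRASE

    def test_minus_strand_position_is_anchor_proximal_boundary(self, genome, pv):
        calls, _ = call_sites(
            [_prepped()], {"r1": [_aln(strand="-", start=7000, span=60)]},
            FilterParams(), genome, pv,
        )
        assert calls[0].position == 7059
        assert calls[0].strand == "-"

    @pytest.mark.parametrize(
        "prepped, alns, reason",
        [
            (
                PreppedRead(id="r1", host_sequence="ACGT" * 20, evidence="merged",
                            ltr_end=None, anchor_found=False),
                [_aln()],
                "no_anchor",
            ),
            (_prepped(splink=True), [_aln()], "splinkerette"),
            (_prepped(), [_aln(span=25)], "short_match"),
            (_prepped(), [], "short_match"),
            (_prepped(), [_aln(coopt=2, mapq=0)], "ambiguous"),
            (_prepped(), [_aln(qstart=3)], "not_junction_adjacent"),
            (_prepped(), [_aln(mapq=20)], "low_mapq"),
            (_prepped(), [_aln(ref="provirus")], "not_host"),
        ],
        ids=["no-anchor", "splinkerette", "short-flank", "unmapped",
             "multi-mapping", "clipped-start", "low-mapq", "provirus-hit"],
    )
    def test_rejection_reasons(self, genome, pv, prepped, alns, reason):
        calls, tally = call_sites(
            [prepped], {"r1": alns}, FilterParams(), genome, pv
        )
        assert calls == []
        assert tally[reason] == 1

    def test_missing_alignment_entry_is_inconsistent(self, genome, pv):
        with pytest.raises(ConsistencyError):
            call_sites([_prepped()], {}, FilterParams(), genome, pv)


class TestClassifyJunction:
    def test_intact_terminus_adjacent_to_host(self, pv):
        assert classify_junction(None, _prepped(host="GGTTGGTT"), pv) == INTEGRASE

    def test_incomplete_anchor_unresolved(self, pv):
        assert classify_junction(None, _prepped(complete=False), pv) == UNRESOLVED

    def test_microhomologous_host_flank_unresolved(self, pv):
        # host flank begins with the terminal dinucleotide: the boundary
        # cannot be assigned to provirus or host
        assert classify_junction(None, _prepped(host="CAGGTT"), pv) == UNRESOLVED


class TestDedup:
    def test_five_reads_at_one_position_collapse(self):
        calls = [
            JunctionCall("chr1", 100, "+", 3, INTEGRASE, "merged", [f"r{i}"])
            for i in range(5)
        ]
        unique = dedup_and_unique(calls)
        assert len(unique) == 1
        assert unique[0].read_ids == [f"r{i}" for i in range(5)]

    def test_adjacent_positions_stay_distinct(self):
        calls = [
            JunctionCall("chr1", 100, "+", 3, INTEGRASE, "merged", ["a"]),
            JunctionCall("chr1", 101, "+", 3, INTEGRASE, "merged", ["b"]),
        ]
        assert len(dedup_and_unique(calls)) == 2

    def test_matches_set_comprehension_oracle(self):
        rng = np.random.default_rng(17)
        calls = [
            JunctionCall(
                f"chr{rng.integers(1, 4)}", int(rng.integers(0, 50)),
                "+-"[rng.integers(0, 2)], (5, 3)[rng.integers(0, 2)],
                INTEGRASE, "merged", [f"r{i}"],
            )
            for i in range(1000)
        ]
        oracle = {(c.chromosome, c.position, c.strand, c.ltr_end) for c in calls}
        unique = dedup_and_unique(calls)
        assert {c.key for c in unique} == oracle
        assert len(unique) == len(oracle)
        assert unique == sorted(unique, key=lambda c: (c.chromosome, c.position))


def _calls_at(positions, chrom="chr1"):
    return [
        JunctionCall(chrom, p, "+", 3, INTEGRASE, "merged", [f"r{i}"])
        for i, p in enumerate(positions)
    ]


def union_find_clusters(positions, radius):
    """Oracle: connected components of the <=radius adjacency graph."""
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(positions):
        for j, b in enumerate(positions):
            if i < j and abs(a - b) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    return sorted(sorted(g) for g in groups.values())


class TestClustering:
    def test_gap_arithmetic(self):
        cs = cluster_positions(_calls_at([100, 300, 700]), radius=250)
        assert [c.positions for c in cs.clusters] == [[100, 300], [700]]

    def test_transitive_chaining(self):
        cs = cluster_positions(_calls_at([0, 200, 400, 600]), radius=250)
        assert len(cs) == 1
        assert cs.clusters[0].size == 4
        assert cs.clusters[0].span == (0, 600)

    def test_single_position(self):
        cs = cluster_positions(_calls_at([1234]), radius=250)
        assert len(cs) == 1 and cs.clusters[0].size == 1

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(23)
        positions = sorted(int(p) for p in rng.integers(0, 200_000, size=400))
        calls = _calls_at(sorted(set(positions)))
        cs = cluster_positions(calls, radius=250)
        assert [c.positions for c in cs.clusters] == union_find_clusters(
            sorted(set(positions)), 250
        )

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(29)
        positions = [int(p) for p in rng.integers(0, 10_000, size=50)]
        calls = _calls_at(positions)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        a = cluster_positions(calls, radius=250)
        b = cluster_positions(shuffled, radius=250)
        assert [c.positions for c in a.clusters] == [c.positions for c in b.clusters]

    def test_count_ordering_property(self):
        rng = np.random.default_rng(31)
        calls = _calls_at([int(p) for p in rng.integers(0, 5_000, size=200)])
        unique = dedup_and_unique(calls)
        clusters = cluster_positions(unique, radius=250)
        assert len(clusters) <= len(unique) <= len(calls)


class TestLibrarySummary:
    def test_percentage_arithmetic(self):
        calls = [
            JunctionCall("chr1", 100 * i, "+", 3,
                         INTEGRASE if i < 3 else UNRESOLVED, "merged", [f"r{i}"])
            for i in range(10)
        ]
        table = library_summary(calls)
        row = table[(table.ltr_end == 3) & (table.evidence == "merged")].iloc[0]
        assert row.integrase_catalyzed == 3
        assert row.unresolved == 7
        assert row.total == 10
        assert row.pct_integrase == 30.0

    def test_empty_input_gives_zero_table(self):
        table = library_summary([])
        assert (table.total == 0).all()
        assert (table.integrase_catalyzed == 0).all()
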