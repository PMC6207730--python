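"""Locus classification, multi-locus grouping and 10-kb cluster calling."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from plantmir.annotation import (
    ClusterConfig, PrecursorLocus, classify_localization, detect_clusters,
    find_multilocus, load_gene_intervals,
)
from plantmir.io import write_gff3


def _locus(pid="p1", chrom="chr1", start=100, end=200, strand="+"):
    return PrecursorLocus(pid, chrom, start, end, strand)


class TestLocalization:
    GENES = {"chr1": [(1_000, 2_000), (5_000, 6_000)]}

    def test_no_genes_on_chromosome_warns_intergenic(self, caplog):
        with caplog.at_level(logging.WARNING, logger="plantmir.annotation"):
            assert classify_localization(_locus(chrom="chrX"), self.GENES) == "intergenic"
        assert "absent" in caplog.text

    def test_inside_gene_is_intragenic(self):
        assert classify_localization(_locus(start=1_200, end=1_300), self.GENES) == "intragenic"

    def test_between_genes_is_intergenic(self):
        assert classify_localization(_locus(start=3_000, end=3_100), self.GENES) == "intergenic"

    @pytest.mark.parametrize("start, end, expected", [
        (900, 1_000, "intragenic"),    # exactly 1 bp overlap at gene start
        (2_000, 2_100, "intragenic"),  # exactly 1 bp overlap at gene end
        (2_001, 2_100, "intergenic"),  # adjacent, no overlap
    ])
    def test_one_bp_overlap_rule(self, start, end, expected):
        assert classify_localization(_locus(start=start, end=end), self.GENES) == expected

    def test_gff3_round_trip(self, tmp_path):
        path = tmp_path / "genes.gff3"
        write_gff3([("chr1", "test", "gene", 10, 50, ".", "+", "ID=g1"),
                    ("chr2", "test", "gene", 5, 9, ".", "-", "ID=g2"),
                    ("chr1", "test", "miRNA", 100, 120, ".", "+", "ID=m1")], path)
        genes = load_gene_intervals(path)
        assert genes == {"chr1": [(10, 50)], "chr2": [(5, 9)]}


class TestMultilocus:
    def test_all_distinct(self):
        groups = find_multilocus([
            ("a", "ACGU", _locus("a")), ("b", "UGCA", _locus("b", start=500, end=600)),
        ])
        assert all(len(v) == 1 for v in groups.values())

    def test_identical_sequence_grouped(self):
        loci = [(f"p{i}", "ACGUACGU", _locus(f"p{i}", start=1000 * i + 1, end=1000 * i + 8))
                for i in range(1, 5)]
        groups = find_multilocus(loci)
        assert len(groups) == 1
        assert len(groups["p1"]) == 4

    def test_one_nt_difference_not_grouped(self):
        groups = find_multilocus([
            ("a", "ACGUACGU", _locus("a")),
            ("b", "ACGUACGA", _locus("b", start=900, end=1000)),
        ])
        assert len(groups) == 2


class TestClusters:
    def _pair(self, gap, strands=("+", "+")):
        first = _locus("p1", start=1_000, end=1_100, strand=strands[0])
        second = _locus("p2", start=1_100 + 1 + gap, end=2_200 + gap, strand=strands[1])
        return [first, second]

    @pytest.mark.parametrize("gap, n_clusters", [(9_999, 1), (10_000, 1), (10_001, 0)])
    def test_gap_boundary_inclusive(self, gap, n_clusters):
        calls = detect_clusters(self._pair(gap))
        assert len(calls) == n_clusters

    def test_antiparallel_flag(self):
        calls = detect_clusters(self._pair(5_000, strands=("+", "-")))
        assert len(calls) == 1 and calls[0].antiparallel

    def test_same_strand_not_antiparallel(self):
        calls = detect_clusters(self._pair(5_000))
        assert not calls[0].antiparallel

    def test_chaining_three_members(self):
        loci = [_locus("p1", start=1, end=100),
                _locus("p2", start=5_000, end=5_100),
                _locus("p3", start=14_000, end=14_100)]
        calls = detect_clusters(loci)
        assert len(calls) == 1 and len(calls[0].member_loci) == 3

    def test_membership_invariant_under_reordering(self):
        loci = [_locus("p1", start=1, end=100),
                _locus("p2", start=5_000, end=5_100),
                _locus("p3", chrom="chr2", start=1, end=100),
                _locus("p4", chrom="chr2", start=2_000, end=2_100)]
        forward = detect_clusters(loci)
        backward = detect_clusters(loci[::-1])
        key = lambda calls: sorted(
            tuple(sorted(l.precursor_id for l in c.member_loci)) for c in calls)
        assert key(forward) == key(backward)

    def test_count_conservation(self):
        loci = [_locus(f"p{i}", start=i * 7_000 + 1, end=i * 7_000 + 100)
                for i in range(10)]
        calls = detect_clusters(loci)
        clustered = sum(len(c.member_loci) for c in calls)
        singles = len(loci) - clustered
        assert clustered + singles == len(loci)

    def test_max_gap_zero_only_bookended(self):
        bookended = [_locus("p1", start=1, end=100), _locus("p2", start=101, end=200)]
        apart = [_locus("p1", start=1, end=100), _locus("p2", start=102, end=200)]
        assert len(detect_clusters(bookended, ClusterConfig(max_gap=0))) == 1
        assert detect_clusters(apart, ClusterConfig(max_gap=0)) == []

    def test_huge_gap_one_cluster_per_chromosome(self):
        loci = [_locus("p1", start=1, end=100),
                _locus("p2", start=900_000, end=900_100),
                _locus("p3", chrom="chr2", start=1, end=100)]
        calls = detect_clusters(loci, ClusterConfig(max_gap=10**9))
        assert len(calls) == 1        # chr2 has a single locus: no cluster
        assert len(calls[0].member_loci) == 2


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 500_000), st.integers(1, 200),
                          st.sampled_from("+-")), min_size=0, max_size=15))
def test_cluster_membership_partitions_loci(spans):
    """Clustered members plus singletons always account for every locus,
    every cluster has >= 2 members and respects the gap bound."""
    loci = [PrecursorLocus(f"p{i}", "chr1", s, s + l, strand)
            for i, (s, l, strand) in enumerate(spans)]
    calls = detect_clusters(loci)
    member_ids = [l.precursor_id for c in calls for l in c.member_loci]
    assert len(member_ids) == len(set(member_ids))
    assert len(member_ids) <= len(loci)
    for c in calls:
        assert len(c.member_loci) >= 2
        ordered = sorted(c.member_loci, key=lambda l: l.start)
        for prev, nxt in zip(ordered, ordered[1:]):
            assert nxt.start - prev.end - 1 <= 10_000


def test_synthetic_truth_annotations_recovered(small_sim):
    """Planted intragenic/cluster structure is recovered from the truth."""
    sim = small_sim["sim"]
    genes = {}
    for chrom, start, end, _gid in sim.genes:
        genes.setdefault(chrom, []).append((start, end))
    for g in genes.values():
        g.sort()
    for p in sim.truth.precursors:
        locus = PrecursorLocus(p.id, p.chrom, p.start, p.end, p.strand)
        expected = "intragenic" if p.is_intragenic else "intergenic"
        assert classify_localization(locus, genes) == expected
    loci = [PrecursorLocus(p.id, p.chrom, p.start, p.end, p.strand)
            for p in sim.truth.precursors]
    calls = detect_clusters(loci)
    clustered_truth = {p.id for p in sim.truth.precursors if p.cluster_id}
    clustered_found = {l.precursor_id for c in calls for l in c.member_loci}
    assert clustered_found == clustered_truth
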