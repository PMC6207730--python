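"""Inverted-repeat discovery and mature-homology scanning."""

import logging

import numpy as np
import pytest

from plantmir.hairpin import (
    HairpinCandidate, HomologyConfig, IRScoringConfig, extract_candidate,
    find_inverted_repeats, scan_mature_homology, family_of,
)
from plantmir.seqs import revcomp_dna

from oracles import ir_best_score


def _planted(stem: str, loop: str, flank_l: str = "AAA", flank_r: str = "AAA") -> str:
    return flank_l + stem + loop + revcomp_dna(stem) + flank_r


def test_poly_a_has_no_repeats():
    assert find_inverted_repeats("A" * 1000) == []


def test_empty_sequence_is_empty_result():
    assert find_inverted_repeats("") == []


def test_alphabet_check():
    with pytest.raises(ValueError):
        find_inverted_repeats("ACGTQ" * 10)


def test_perfect_13bp_stem_scores_39():
    seq = _planted("GATCCGGATCAGT", "TTAGCAGC")
    repeats = find_inverted_repeats(seq)
    assert len(repeats) == 1
    r = repeats[0]
    assert r.score == 39                       # 13 matches x +3
    assert r.left_arm == (4, 16)
    assert r.right_arm == (25, 37)
    assert r.loop == (17, 24)
    assert all(state == "match" for _, _, state in r.arm_alignment)


def test_8bp_stem_is_below_threshold():
    seq = _planted("GATCCGGA", "TTAGC")
    assert find_inverted_repeats(seq) == []    # 8 x 3 = 24 < 25


def test_n_never_matches():
    seq = _planted("GATCCGGATCAGT", "TTAGCAGC").replace("GATCCGGATCAGT", "NNNNNNNNNNNNN", 1)
    assert find_inverted_repeats(seq) == []


def test_score_equals_alignment_score_under_config():
    cfg = IRScoringConfig()
    seq = _planted("GATCCGGATCAGTAA", "TTAGCAGC")
    for r in find_inverted_repeats(seq, cfg):
        recomputed = sum(
            cfg.match_score if state == "match"
            else (cfg.mismatch_score if state == "mismatch" else cfg.gap_penalty)
            for _, _, state in r.arm_alignment
        )
        assert recomputed == r.score
        assert r.span <= cfg.max_extent


def test_agrees_with_quadratic_oracle_on_random_sequences():
    """Best reported score equals an exhaustive arm-pairing DP (<= 200 nt)."""
    rng = np.random.default_rng(7)
    checked_nonempty = 0
    for _ in range(40):
        n = int(rng.integers(40, 200))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        oracle = ir_best_score(seq)
        repeats = find_inverted_repeats(seq)
        if oracle >= 25:
            assert repeats, f"oracle {oracle} but no repeat found"
            assert max(r.score for r in repeats) == oracle
            checked_nonempty += 1
        else:
            assert repeats == []
    assert checked_nonempty >= 5


def test_reverse_complement_symmetry():
    rng = np.random.default_rng(3)
    stem = "".join(rng.choice(list("ACGT"), size=14))
    seq = "CATG" + _planted(stem, "TCTAGA") + "TTGACC"
    fwd = find_inverted_repeats(seq)
    rev = find_inverted_repeats(revcomp_dna(seq))
    n = len(seq)
    mirrored = sorted((n - r.end + 1, n - r.start + 1, r.score) for r in rev)
    assert sorted((r.start, r.end, r.score) for r in fwd) == mirrored


def test_planted_recall_on_synthetic_truth(small_sim):
    """Every planted precursor overlaps a reported repeat."""
    sim = small_sim["sim"]
    for chrom, seq in sim.genome.items():
        repeats = find_inverted_repeats(seq, chrom=chrom)
        for p in sim.truth.precursors:
            if p.chrom != chrom:
                continue
            assert any(r.start <= p.end and p.start <= r.end for r in repeats), p.id


class TestExtractCandidate:
    def _repeat(self, genome):
        return find_inverted_repeats(genome["chr1"], chrom="chr1")[0]

    def test_flank_zero_length_equals_span(self):
        genome = {"chr1": "T" * 50 + _planted("GATCCGGATCAGT", "TTAGCAGC") + "T" * 50}
        r = self._repeat(genome)
        cand = extract_candidate(r, genome)
        assert len(cand.sequence) == r.span
        assert set(cand.sequence) <= set("ACGU")

    def test_flank_extends_both_sides(self):
        genome = {"chr1": "T" * 50 + _planted("GATCCGGATCAGT", "TTAGCAGC") + "T" * 50}
        r = self._repeat(genome)
        cand = extract_candidate(r, genome, flank=10)
        assert len(cand.sequence) == r.span + 20

    def test_truncation_warns(self, caplog):
        genome = {"chr1": _planted("GATCCGGATCAGT", "TTAGCAGC", flank_l="", flank_r="")}
        r = self._repeat(genome)
        with caplog.at_level(logging.WARNING, logger="plantmir.hairpin"):
            cand = extract_candidate(r, genome, flank=10)
        assert cand.start == 1
        assert "truncated" in caplog.text

    def test_minus_strand_is_reverse_complement(self):
        genome = {"chr1": "T" * 30 + _planted("GATCCGGATCAGT", "TTAGCAGC") + "T" * 30}
        r = self._repeat(genome)
        plus = extract_candidate(r, genome, strand="+")
        minus = extract_candidate(r, genome, strand="-")
        assert minus.sequence == plus.sequence.translate(
            str.maketrans("ACGU", "UGCA"))[::-1]


class TestMatureHomology:
    REF = "UGGAAGCUAGGUAAGGCUCAU"   # 21 nt

    def _candidate(self, seq):
        return HairpinCandidate(id="c", chrom="chr1", start=1, end=len(seq),
                                strand="+", sequence=seq,
                                loop_mid_offset=len(seq) // 2)

    def _with_substitutions(self, k):
        mutated = list(self.REF)
        swap = {"U": "A", "G": "C", "A": "U", "C": "G"}
        for i in range(k):
            mutated[2 * i] = swap[mutated[2 * i]]
        return "".join(mutated)

    def test_exact_copy_hits_with_zero_mismatches(self):
        cand = self._candidate("A" * 20 + self.REF + "A" * 20)
        hits = scan_mature_homology(cand, {"osa-miR168a-5p": self.REF})
        assert len(hits) == 1
        assert hits[0].mismatches == 0
        assert hits[0].offset == 20
        assert hits[0].family == "miR168a"

    @pytest.mark.parametrize("k, expected", [(5, 1), (6, 0)])
    def test_mismatch_boundary(self, k, expected):
        cand = self._candidate("A" * 20 + self._with_substitutions(k) + "A" * 20)
        hits = scan_mature_homology(cand, {"ref-miR1": self.REF})
        assert len(hits) == expected
        if expected:
            assert hits[0].mismatches == k

    def test_arm_assignment(self):
        seq = self.REF + "GAGA" * 5 + "A" * 21
        cand = self._candidate(seq)
        hits = scan_mature_homology(cand, {"m-miR2": self.REF})
        assert hits[0].arm == "5p"
        seq2 = "A" * 21 + "GAGA" * 5 + self.REF
        hits2 = scan_mature_homology(self._candidate(seq2), {"m-miR2": self.REF})
        assert hits2[0].arm == "3p"

    def test_bad_reference_named_in_error(self):
        cand = self._candidate("A" * 60)
        with pytest.raises(ValueError, match="bad-rec"):
            scan_mature_homology(cand, {"bad-rec": "ACGUX" * 4 + "A"})

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            scan_mature_homology(self._candidate("A" * 60), {})


def test_family_parsing():
    assert family_of("sly-miR167a-5p") == "miR167a"
    assert family_of("no-family-here") == "no-family-here"
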