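"""Synthetic-data generators: planted truth, invariants, determinism."""

import json

import numpy as np
import pytest

from plantmir.descriptors import FilterConfig, apply_filters, compute_descriptors
from plantmir.folding import fold_fallback
from plantmir.hairpin import find_inverted_repeats
from plantmir.seqs import hamming, revcomp_rna, rna_to_dna, revcomp_dna
from plantmir.synthetic import (
    TruthTable, designed_expectation, generate_genome, generate_mature_reference,
    generate_qpcr_tables, generate_target_transcriptome,
)


def test_empty_case_yields_plain_chromosome():
    sim = generate_genome(1, 100_000, 0, seed=7)
    assert list(sim.genome) == ["chr1"]
    assert len(sim.genome["chr1"]) == 100_000
    assert sim.truth.precursors == []
    assert sim.genes == []


def test_infeasible_packing_is_explicit_error():
    with pytest.raises(ValueError, match="infeasible"):
        generate_genome(1, 5_000, 10, seed=0)


def test_rounding_rule_counts(small_sim):
    truth = small_sim["truth"]
    assert len(truth.precursors) == 6
    assert sum(p.is_intragenic for p in truth.precursors) == 1    # round(0.2*6)
    assert sum(p.cluster_id is not None for p in truth.precursors) == 2


def test_determinism_is_byte_identical(tmp_path):
    runs = []
    for sub in ("a", "b"):
        sim = generate_genome(1, 60_000, 3, seed=9)
        paths = sim.write(tmp_path / sub)
        runs.append({name: p.read_bytes() for name, p in paths.items()})
    assert runs[0] == runs[1]


class TestPlantedInvariants:
    def test_matures_occur_verbatim(self, small_sim):
        for p in small_sim["truth"].precursors:
            assert p.sequence[p.mature_5p_offset:
                              p.mature_5p_offset + len(p.mature_5p)] == p.mature_5p
            assert p.sequence[p.mature_3p_offset:
                              p.mature_3p_offset + len(p.mature_3p)] == p.mature_3p
            assert 70 <= len(p.sequence) <= 300
            assert 20 <= len(p.mature_5p) <= 24

    def test_sequence_matches_genome_coordinates(self, small_sim):
        sim = small_sim["sim"]
        for p in sim.truth.precursors:
            genomic = sim.genome[p.chrom][p.start - 1:p.end]
            expected = rna_to_dna(p.sequence)
            if p.strand == "-":
                expected = revcomp_dna(expected)
            assert genomic == expected

    def test_arms_mostly_reverse_complementary(self, small_sim):
        """The planted 5p/3p matures pair over >= 60% of their length."""
        for p in small_sim["truth"].precursors:
            d = hamming(p.mature_5p, revcomp_rna(p.mature_3p))
            assert d / len(p.mature_5p) <= 0.4
            assert d >= 1     # but never perfectly palindromic (strand stays resolvable)

    def test_every_precursor_passes_filter_cascade_with_fallback(self, small_sim):
        for p in small_sim["truth"].precursors:
            fold = fold_fallback(p.sequence)
            desc = compute_descriptors(p.sequence, fold)
            verdict = apply_filters(desc, ["planted"], FilterConfig())
            assert verdict.passed, (p.id, verdict.failed_rules)
            assert find_inverted_repeats(rna_to_dna(p.sequence)), p.id

    def test_decoys_do_not_overlap_precursors_and_are_hairpin_free(self, small_sim):
        sim = small_sim["sim"]
        assert sim.truth.decoy_regions
        for chrom, start, end in sim.truth.decoy_regions:
            for p in sim.truth.precursors:
                assert not (p.chrom == chrom and p.start <= end and start <= p.end)
            assert find_inverted_repeats(sim.genome[chrom][start - 1:end]) == []

    def test_gene_features_cover_exactly_the_intragenic(self, small_sim):
        sim = small_sim["sim"]
        for p in sim.truth.precursors:
            covered = any(
                chrom == p.chrom and start <= p.start and p.end <= end
                for chrom, start, end, _gid in sim.genes
            )
            assert covered == p.is_intragenic, p.id


def test_multilocus_copies_planted_verbatim():
    sim = generate_genome(2, 60_000, 3, frac_intragenic=0.0, frac_clustered=0.0,
                          seed=13, n_multilocus=1, copies_per_multilocus=3)
    p = sim.truth.precursors[0]
    assert len(p.copy_loci) == 2
    for chrom, start, end, strand in p.copy_loci:
        genomic = sim.genome[chrom][start - 1:end]
        expected = rna_to_dna(p.sequence)
        if strand == "-":
            expected = revcomp_dna(expected)
        assert genomic == expected


class TestMatureReference:
    def test_no_decoys_gives_only_planted(self, small_sim):
        refs = generate_mature_reference(small_sim["truth"], 0)
        assert len(refs) == 12      # 6 precursors x 2 arms

    def test_decoys_distinct_from_planted_by_hamming(self, small_sim):
        refs = generate_mature_reference(small_sim["truth"], 20, seed=3)
        planted = list(small_sim["truth"].matures().values())
        decoys = [s for name, s in refs.items() if name.startswith("decoy")]
        assert len(decoys) == 20
        for d in decoys:
            for p in planted:
                if len(p) == len(d):
                    assert hamming(p, d) > 5

    def test_deterministic(self, small_sim):
        a = generate_mature_reference(small_sim["truth"], 20, seed=3)
        b = generate_mature_reference(small_sim["truth"], 20, seed=3)
        assert a == b

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError):
            generate_mature_reference(TruthTable(), 5)


class TestTargetTranscriptome:
    def test_perfect_site_is_exact_reverse_complement(self, small_sim):
        truth = small_sim["truth"]
        matures = truth.matures()
        perfect = [s for s in truth.target_sites if not s.edits]
        assert perfect
        for site in perfect:
            tx = small_sim["transcripts"][site.transcript_id]
            m = matures[site.mirna_id]
            window = tx[site.position - 1:site.position - 1 + len(m)]
            assert window == revcomp_rna(m)

    def test_designed_scores_follow_penalty_table(self, small_sim):
        for site in small_sim["truth"].target_sites:
            m = small_sim["truth"].matures()[site.mirna_id]
            assert site.designed_expectation == designed_expectation(m, site.edits)

    def test_extra_perfect_sites_counted(self):
        sim = generate_genome(1, 40_000, 2, frac_intragenic=0, frac_clustered=0, seed=21)
        mid = f"{sim.truth.precursors[0].id}-5p"
        tx = generate_target_transcriptome(sim.truth, seed=21,
                                           extra_perfect={mid: 30})
        n_perfect = sum(1 for s in sim.truth.target_sites
                        if s.mirna_id == mid and not s.edits)
        assert n_perfect == 31        # 1 graded perfect + 30 extra
        assert len(tx) == len(sim.truth.target_sites)


class TestQpcrTables:
    def test_noiseless_dilution_step_for_e1(self):
        dilution, _ = generate_qpcr_tables({"g": 1.0}, {"g": 1.0}, seed=1)
        cqs = dilution[dilution.gene == "g"].sort_values("dilution_step")["cq"].to_numpy()
        steps = np.diff(cqs)
        assert np.allclose(steps, np.log10(5) / np.log10(2))   # 2.3219 per 1:5 step

    def test_deterministic(self):
        a = generate_qpcr_tables({"g": 0.9}, {"g": 2.0}, noise_sd=0.3, seed=8)
        b = generate_qpcr_tables({"g": 0.9}, {"g": 2.0}, noise_sd=0.3, seed=8)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_efficiency_bounds_validated(self):
        with pytest.raises(ValueError):
            generate_qpcr_tables({"g": 1.5}, {"g": 1.0})

    def test_unit_folds_give_unit_ratio_downstream(self):
        from plantmir.qpcr import fit_dilution_table, relative_expression
        dilution, expression = generate_qpcr_tables(
            {"a": 0.9, "b": 1.1, "U6": 1.0, "5.8S": 1.0},
            {"a": 1.0, "b": 1.0}, seed=4)
        eff = {g: c.efficiency for g, c in fit_dilution_table(dilution).items()}
        for r in relative_expression(expression, eff, ["U6", "5.8S"], "leaf"):
            assert r.ratio == pytest.approx(1.0, abs=1e-9)


def test_truth_table_json_round_trip(small_sim, tmp_path):
    truth = small_sim["truth"]
    path = tmp_path / "truth.json"
    truth.to_json(path)
    loaded = TruthTable.from_json(path)
    assert loaded == truth
    assert json.loads(path.read_text())["qpcr_truth"] == {}
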