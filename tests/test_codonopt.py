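"""Divergence-maximizing codon optimization and silencing-escape checks."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from silencereplace import synth
from silencereplace.codonopt import (
    OptimizationConstraints,
    OptimizationError,
    hamming,
    max_divergent_codon,
    optimize_cds,
    verify_escape,
)
from silencereplace.guidewalk import GuideCandidate, enumerate_guides, mismatch_positions
from silencereplace.seqcore import CodonTable, NamedSequence, revcomp, translate

TABLE = CodonTable.human()
CONSTRAINTS = OptimizationConstraints()

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
NON_STOP = [c for c in ALL_CODONS if TABLE.code[c] != "*"]


def oracle_max_divergent(codon: str, min_freq: float = 0.10) -> str:
    """Exhaustive per-codon brute force implementing the selection rule:
    max Hamming distance, then higher relative usage, then lexicographic,
    over synonyms passing the usage floor (unfiltered as fallback)."""
    syn = [c for c in ALL_CODONS if TABLE.code[c] == TABLE.code[codon]]
    passing = [c for c in syn if TABLE.usage[c] >= min_freq] or syn
    return min(passing, key=lambda c: (-hamming(codon, c), -TABLE.usage[c], c))


class TestMaxDivergentCodon:
    def test_single_codon_amino_acid_unchanged(self):
        assert max_divergent_codon("ATG", TABLE) == "ATG"  # Met
        assert max_divergent_codon("TGG", TABLE) == "TGG"  # Trp

    def test_serine_goes_to_distance_three(self):
        # brute force over the 6 Ser codons: TCT/TCA/TCG are at distance 3
        # from AGC; TCT wins the usage tie-break (0.19 > 0.15 > 0.05)
        chosen = max_divergent_codon("AGC", TABLE)
        assert chosen == oracle_max_divergent("AGC") == "TCT"
        assert hamming("AGC", chosen) == 3

    def test_lysine_two_codon_family(self):
        # brute force over the 2 Lys codons
        assert max_divergent_codon("AAA", TABLE) == oracle_max_divergent("AAA") == "AAG"
        assert hamming("AAA", "AAG") == 1

    def test_stop_codon_rejected(self):
        with pytest.raises(OptimizationError, match="stop"):
            max_divergent_codon("TAA", TABLE)

    @pytest.mark.parametrize("codon", NON_STOP)
    def test_equals_exhaustive_bruteforce_for_every_codon(self, codon):
        assert max_divergent_codon(codon, TABLE) == oracle_max_divergent(codon)

    def test_preserves_amino_acid_always(self):
        for codon in NON_STOP:
            assert TABLE.code[max_divergent_codon(codon, TABLE)] == TABLE.code[codon]


class TestOptimizeCds:
    def test_toy_cds_frozen_oracle_values(self):
        # M K S *: per-codon oracle gives ATG AAG TCT; stop untouched.
        # Positional identity: ATG(3) + AAA/AAG(2) + AGC/TCT(0) + TAA(3) = 8/12
        opt = optimize_cds(NamedSequence("t", "ATGAAAAGCTAA"))
        assert opt.dna == "ATG" + "AAG" + "TCT" + "TAA"
        assert opt.identity_to_wt == pytest.approx(8 / 12)
        assert opt.changed_positions == 4

    def test_protein_preserved_on_receptor_scale_cds(self):
        wt, _ = synth.make_receptor_like_cds()
        opt = optimize_cds(wt)
        assert translate(opt.dna) == translate(wt.residues)
        assert opt.identity_to_wt < 0.74

    def test_reoptimization_preserves_protein(self, orf_alleles):
        once = optimize_cds(orf_alleles.wt_cds)
        twice = optimize_cds(NamedSequence("o", once.dna))
        assert translate(twice.dna) == translate(orf_alleles.wt_cds.residues)

    def test_deterministic(self, orf_alleles):
        assert optimize_cds(orf_alleles.wt_cds).dna == optimize_cds(orf_alleles.wt_cds).dna

    def test_no_forbidden_motif_in_output(self):
        # a CDS that starts out containing PstI (CTGCAG) and a homopolymer
        wt = NamedSequence("m", "ATG" + "CTG" + "CAG" + "AAA" + "AAA" + "GGC" + "TAA")
        opt = optimize_cds(wt)
        for motif in CONSTRAINTS.forbidden_motifs:
            assert motif not in opt.dna
        assert translate(opt.dna) == translate(wt.residues)

    @given(seed=st.integers(min_value=0, max_value=60))
    def test_protein_preservation_property(self, seed):
        alleles = synth.make_toy_allele_set(synth.SimulationConfig(seed=seed, cds_length=150))
        opt = optimize_cds(alleles.wt_cds)
        assert translate(opt.dna) == translate(alleles.wt_cds.residues)
        for motif in CONSTRAINTS.forbidden_motifs:
            assert motif not in opt.dna

    def test_greedy_matches_bruteforce_where_no_repair_fired(self, orf_alleles):
        """Outside the codons the repair pass touched, every output codon
        equals the exhaustive per-codon brute force choice; the greedy
        pass itself reproduces the oracle everywhere."""
        wt = orf_alleles.wt_cds.residues
        opt = optimize_cds(orf_alleles.wt_cds)
        repaired = set(opt.repaired_codons)
        for ci in range(len(wt) // 3):
            if ci + 1 in repaired:
                continue
            codon, chosen = wt[3 * ci : 3 * ci + 3], opt.dna[3 * ci : 3 * ci + 3]
            expected = codon if TABLE.code[codon] == "*" else oracle_max_divergent(codon)
            assert chosen == expected, f"codon {ci + 1} deviates outside any repair region"

    def test_relaxing_usage_floor_never_increases_identity(self, orf_alleles):
        strict = optimize_cds(
            orf_alleles.wt_cds, constraints=OptimizationConstraints(min_relative_codon_freq=0.5)
        )
        relaxed = optimize_cds(
            orf_alleles.wt_cds, constraints=OptimizationConstraints(min_relative_codon_freq=0.0)
        )
        assert relaxed.identity_to_wt <= strict.identity_to_wt


class TestVerifyEscape:
    def test_planted_target_window_fails(self, orf_alleles):
        guide = enumerate_guides(orf_alleles, snp_offset_range=(6, 6))[0]
        opt = optimize_cds(orf_alleles.wt_cds)
        planted = opt.dna[:30] + revcomp(guide.guide_seq) + opt.dna[30:]
        report = verify_escape(planted, [guide])
        entry = report.entries[0]
        assert entry.min_mismatches == 0
        assert not entry.passed
        assert not report.overall_pass

    def test_empty_guide_list_passes_vacuously(self, orf_alleles):
        report = verify_escape(optimize_cds(orf_alleles.wt_cds).dna, [])
        assert report.entries == ()
        assert report.overall_pass

    def test_min_mismatches_equals_exhaustive_window_scan(self, orf_alleles):
        opt = optimize_cds(orf_alleles.wt_cds)
        guides = enumerate_guides(orf_alleles)
        report = verify_escape(opt.dna, guides)
        for guide, entry in zip(guides, report.entries):
            L = len(guide)
            oracle = min(
                len(mismatch_positions(guide.guide_seq, opt.dna[i : i + L]))
                for i in range(len(opt.dna) - L + 1)
            )
            assert entry.min_mismatches == oracle

    @given(seed=st.integers(min_value=0, max_value=40))
    def test_escape_report_matches_oracle_on_random_cases(self, seed):
        alleles = synth.make_toy_allele_set(synth.SimulationConfig(seed=seed, cds_length=150))
        guide = enumerate_guides(alleles, snp_offset_range=(8, 8))[0]
        opt = optimize_cds(alleles.wt_cds)
        entry = verify_escape(opt.dna, [guide]).entries[0]
        L = len(guide)
        mms = [
            len(mismatch_positions(guide.guide_seq, opt.dna[i : i + L]))
            for i in range(len(opt.dna) - L + 1)
        ]
        assert entry.min_mismatches == min(mms)
        assert entry.worst_window_start == mms.index(min(mms)) + 1
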