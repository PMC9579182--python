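"""Sequence-walk enumeration, mismatch engineering, and scoring."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from silencereplace import synth
from silencereplace.guidewalk import (
    GuideCandidate,
    GuideError,
    MismatchRule,
    PositionWeightModel,
    candidate_table,
    engineer_mismatch,
    enumerate_guides,
    mismatch_positions,
    offtarget_seed_scan,
    rank_candidates,
    score_potency,
    score_selectivity,
)
from silencereplace.seqcore import NamedSequence, revcomp

MODEL = PositionWeightModel()  # pos1=0.05, seed=0.40, central=0.30, suppl=0.10, cap=1.0

# hand-derived worked example: mutant window 7..13 of the c.10T>A toy,
# guide length 7, SNP at guide position 4
TOY_GUIDE = GuideCandidate("amiR-toy", "TAATCCC", target_span=(7, 13), snp_offset=4)


class TestWorkedExample:
    def test_guide_is_revcomp_of_mutant_window(self, toy_alleles):
        window = toy_alleles.mut_cds.slice1(7, 13)
        assert window == "GGGATTA"
        assert TOY_GUIDE.guide_seq == revcomp(window)

    def test_one_mismatch_vs_wt_window(self, toy_alleles):
        wt_window = toy_alleles.wt_cds.slice1(7, 13)
        assert wt_window == "GGGTTTA"
        assert mismatch_positions(TOY_GUIDE.guide_seq, wt_window) == [4]


class TestEnumerateGuides:
    def test_default_walk_yields_twelve_candidates(self, orf_alleles):
        guides = enumerate_guides(orf_alleles)
        assert len(guides) == 12
        assert [g.snp_offset for g in guides] == list(range(2, 14))
        assert [g.name for g in guides] == [f"amiR-RH{i}" for i in range(1, 13)]

    def test_every_candidate_is_revcomp_of_its_window(self, orf_alleles):
        for g in enumerate_guides(orf_alleles):
            window = orf_alleles.mut_cds.slice1(*g.target_span)
            assert g.guide_seq == revcomp(window)
            # pairing convention: guide position snp_offset covers the SNP
            assert g.target_span[1] - g.snp_offset + 1 == orf_alleles.mutation.cds_position

    def test_single_offset_yields_single_candidate(self, orf_alleles):
        guides = enumerate_guides(orf_alleles, snp_offset_range=(5, 5))
        assert len(guides) == 1 and guides[0].snp_offset == 5

    def test_out_of_sequence_windows_skipped(self):
        # SNP near the 5' end: small offsets push the window past the start
        alleles = synth.make_toy_allele_set(
            synth.SimulationConfig(seed=2, cds_length=120, snp_codon=2)
        )
        guides = enumerate_guides(alleles, guide_len=15, snp_offset_range=(2, 13))
        assert 0 < len(guides) < 12
        for g in guides:
            assert g.target_span[0] >= 1

    def test_short_guide_rejected(self, orf_alleles):
        with pytest.raises(GuideError, match=">= 15"):
            enumerate_guides(orf_alleles, guide_len=7)


class TestEngineerMismatch:
    def test_none_rule_is_identity(self):
        assert engineer_mismatch(TOY_GUIDE, MismatchRule.none()) == TOY_GUIDE

    def test_substitution_recorded_and_counts_shift(self, toy_alleles):
        modified = engineer_mismatch(TOY_GUIDE, MismatchRule(7, "A"))
        assert modified.guide_seq == "TAATCCA"
        assert modified.engineered_mismatches == ((7, "A"),)
        mut_window = toy_alleles.mut_cds.slice1(7, 13)
        wt_window = toy_alleles.wt_cds.slice1(7, 13)
        assert len(mismatch_positions(modified.guide_seq, mut_window)) == 1
        assert len(mismatch_positions(modified.guide_seq, wt_window)) == 2

    def test_reverting_restores_mutant_complement(self, toy_alleles):
        modified = engineer_mismatch(TOY_GUIDE, MismatchRule(7, "A"))
        assert revcomp(modified.without_engineered_mismatches()) == (
            toy_alleles.mut_cds.slice1(7, 13)
        )

    def test_existing_base_returned_unchanged(self):
        unchanged = engineer_mismatch(TOY_GUIDE, MismatchRule(1, "T"))
        assert unchanged == TOY_GUIDE
        assert unchanged.engineered_mismatches == ()

    def test_snp_position_rejected(self):
        with pytest.raises(GuideError, match="snp_offset"):
            engineer_mismatch(TOY_GUIDE, MismatchRule(4, "A"))

    def test_out_of_range_rejected(self):
        with pytest.raises(GuideError, match="outside guide"):
            engineer_mismatch(TOY_GUIDE, MismatchRule(8, "A"))


class TestScorePotency:
    def test_perfect_complementarity_scores_one(self, toy_alleles):
        assert score_potency(TOY_GUIDE, toy_alleles.mut_cds.slice1(7, 13), MODEL) == 1.0

    def test_single_central_mismatch_hand_sum(self):
        guide = "A" * 22
        target = revcomp(guide)
        # break pairing at guide position 10 (central, weight 0.30)
        broken = target[:12] + "A" + target[13:]  # target pos 13 pairs guide pos 10
        assert score_potency(guide, broken, MODEL) == pytest.approx(0.70)

    def test_all_mismatched_floors_at_zero(self):
        guide = "A" * 22
        assert score_potency(guide, "A" * 22, MODEL) == 0.0  # A cannot pair A

    def test_length_mismatch_rejected(self):
        with pytest.raises(GuideError, match="length"):
            score_potency("ACGT" * 5, "ACGT", MODEL)

    @given(n_breaks=st.integers(min_value=0, max_value=22))
    def test_monotone_nonincreasing_in_mismatches(self, n_breaks):
        guide = "ACGT" * 5 + "AC"
        target = revcomp(guide)
        rotate = {"A": "C", "C": "G", "G": "T", "T": "A"}
        # break pairings left to right (any substitution of the paired
        # base is a mismatch); potency must never increase
        prev = 1.0
        for k in range(n_breaks + 1):
            broken = "".join(
                rotate[target[i]] if i < k else target[i] for i in range(len(target))
            )
            pot = score_potency(guide, broken, MODEL)
            assert pot <= prev + 1e-12
            prev = pot


class TestScoreSelectivity:
    def test_seed_snp_hand_computation(self):
        # SNP at guide seed position 5, no engineered mismatch:
        # potency_mut 1.0, potency_wt 1 - 0.40 = 0.60, selectivity 0.40
        alleles = synth.make_toy_allele_set(synth.SimulationConfig(seed=3))
        guide = enumerate_guides(alleles, snp_offset_range=(5, 5))[0]
        score = score_selectivity(guide, alleles, MODEL)
        assert score.potency_mut == pytest.approx(1.0)
        assert score.potency_wt == pytest.approx(0.60)
        assert score.selectivity_index == pytest.approx(0.40)

    def test_supplementary_mismatch_lowers_both_potencies_equally(self):
        alleles = synth.make_toy_allele_set(synth.SimulationConfig(seed=3))
        guide = enumerate_guides(alleles, snp_offset_range=(5, 5))[0]
        sub_base = "A" if guide.guide_seq[13] != "A" else "C"
        modified = engineer_mismatch(guide, MismatchRule(14, sub_base))
        score = score_selectivity(modified, alleles, MODEL)
        assert score.potency_mut == pytest.approx(0.90)
        assert score.potency_wt == pytest.approx(0.50)
        assert score.selectivity_index == pytest.approx(0.40)

    def test_guide_missing_snp_has_zero_selectivity(self, orf_alleles):
        # place a window upstream of the SNP so wt == mut there
        snp = orf_alleles.mutation.cds_position
        start, end = snp - 40, snp - 19
        window = orf_alleles.mut_cds.slice1(start, end)
        assert window == orf_alleles.wt_cds.slice1(start, end)
        guide = GuideCandidate("g", revcomp(window), (start, end), snp_offset=1)
        score = score_selectivity(guide, orf_alleles, MODEL)
        assert score.selectivity_index == 0.0

    def test_absent_opt_reported_as_none(self, orf_alleles):
        guide = enumerate_guides(orf_alleles, snp_offset_range=(5, 5))[0]
        assert score_selectivity(guide, orf_alleles, MODEL).potency_opt is None

    @given(seed=st.integers(min_value=0, max_value=30),
           offset=st.integers(min_value=2, max_value=13))
    def test_snp_covering_guides_always_selective(self, seed, offset):
        alleles = synth.make_toy_allele_set(synth.SimulationConfig(seed=seed))
        guides = enumerate_guides(alleles, snp_offset_range=(offset, offset))
        score = score_selectivity(guides[0], alleles, MODEL)
        assert score.selectivity_index > 0


class TestOfftargetScan:
    def test_empty_transcriptome(self):
        assert offtarget_seed_scan(TOY_GUIDE, []) == []
        assert offtarget_seed_scan(TOY_GUIDE, None) == []

    def test_planted_seed_site_recovered(self, orf_alleles):
        guide = enumerate_guides(orf_alleles, snp_offset_range=(5, 5))[0]
        site = revcomp(guide.seed)
        tx = NamedSequence("planted", "ATGATGATGA" + site + "CCCGGGAAA")
        hits = offtarget_seed_scan(guide, [tx])
        assert hits == [("planted", 11)]

    def test_full_complement_contains_seed_site(self, orf_alleles):
        guide = enumerate_guides(orf_alleles, snp_offset_range=(5, 5))[0]
        tx = NamedSequence("target", revcomp(guide.guide_seq))
        hits = offtarget_seed_scan(guide, [tx])
        # seed (guide 2-8) maps to target positions L-7..L-1
        assert (("target", len(guide) - 7)) in hits

    @given(seed=st.integers(min_value=0, max_value=50))
    def test_agrees_with_naive_substring_oracle(self, seed):
        alleles = synth.make_toy_allele_set(synth.SimulationConfig(seed=seed))
        guide = enumerate_guides(alleles, snp_offset_range=(7, 7))[0]
        txs = synth.make_decoy_transcriptome(
            synth.SimulationConfig(seed=seed, n_transcripts=10, transcript_length=200)
        )
        site = revcomp(guide.seed)
        oracle = [
            (tx.id, i + 1)
            for tx in txs
            for i in range(len(tx.residues) - len(site) + 1)
            if tx.residues[i : i + len(site)] == site
        ]
        assert offtarget_seed_scan(guide, txs) == oracle


class TestRanking:
    def test_ranking_deterministic_and_table_schema(self, orf_alleles):
        guides = enumerate_guides(orf_alleles)
        scored = [(g, score_selectivity(g, orf_alleles, MODEL)) for g in guides]
        ranked = rank_candidates(scored)
        assert rank_candidates(list(reversed(scored))) == ranked
        selectivities = [s.selectivity_index for _, s in ranked]
        assert selectivities == sorted(selectivities, reverse=True)
        table = candidate_table(scored)
        assert list(table.columns) == [
            "name", "guide_seq", "target_span", "snp_offset", "mismatches", "gc",
            "potency_mut", "potency_wt", "potency_opt", "selectivity", "offtargets",
        ]
        assert len(table) == 12
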