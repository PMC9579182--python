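"""Sequence-walk guide enumeration, selectivity mismatch engineering, scoring.

The sequence walk tiles antisense guides across the discriminating SNP
so that the SNP occupies successive guide positions (the ``snp_offset``,
counted 5'->3' on the guide). Base-pairing convention: guide position
``i`` pairs with target position ``span.end - i + 1``, i.e. a guide is
the exact reverse complement of its mutant target window before any
engineered mismatch is introduced.

Potency against a window is a heuristic position-weighted mismatch
penalty: mismatches in the seed (guide positions 2-8) cost most, the
central region (9-12) next, the supplementary region (13..L) least.
Selectivity is the potency gap between the mutant and wild-type windows;
a guide covering the SNP is always selective under positive weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .alleles import AlleleSet
from .seqcore import NamedSequence, gc_fraction, revcomp

log = logging.getLogger(__name__)

SEED_RANGE = (2, 8)  # guide positions forming the seed, inclusive


class GuideError(ValueError):
    pass


@dataclass(frozen=True)
class GuideCandidate:
    """One antisense guide from the sequence walk (5'->3')."""

    name: str
    guide_seq: str
    target_span: tuple[int, int]  # 1-based inclusive on the mutant mRNA/CDS
    snp_offset: int  # guide position pairing the SNP, 5'->3'
    engineered_mismatches: tuple[tuple[int, str], ...] = ()
    engineered_originals: tuple[str, ...] = ()  # bases replaced, aligned with the above

    def __post_init__(self) -> None:
        start, end = self.target_span
        if end - start + 1 != len(self.guide_seq):
            raise GuideError(
                f"target span {start}..{end} length does not match guide length "
                f"{len(self.guide_seq)}"
            )
        if not (1 <= self.snp_offset <= len(self.guide_seq)):
            raise GuideError(f"snp_offset {self.snp_offset} outside guide 1..{len(self.guide_seq)}")
        if len(self.engineered_mismatches) != len(self.engineered_originals):
            raise GuideError("engineered mismatch records out of sync with original bases")

    def __len__(self) -> int:
        return len(self.guide_seq)

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.guide_seq)

    @property
    def seed(self) -> str:
        """Guide seed, positions 2-8 (5'->3')."""
        return self.guide_seq[SEED_RANGE[0] - 1 : SEED_RANGE[1]]

    def without_engineered_mismatches(self) -> str:
        """Guide sequence with engineered substitutions reverted, i.e.
        the exact reverse complement of the mutant target window."""
        seq = list(self.guide_seq)
        for (pos, _sub), orig in zip(self.engineered_mismatches, self.engineered_originals):
            seq[pos - 1] = orig
        return "".join(seq)


def mismatch_positions(guide_seq: str, target_window: str) -> list[int]:
    """Guide positions (1-based, 5'->3') not Watson-Crick paired with the
    target window under the reverse-complement pairing convention."""
    if len(guide_seq) != len(target_window):
        raise GuideError(
            f"guide length {len(guide_seq)} != target window length {len(target_window)}"
        )
    rc = revcomp(target_window)  # position i of rc pairs guide position i
    return [i + 1 for i, (g, t) in enumerate(zip(guide_seq, rc)) if g != t]


def enumerate_guides(
    alleles: AlleleSet,
    guide_len: int = 22,
    snp_offset_range: tuple[int, int] = (2, 13),
    name_prefix: str = "amiR-RH",
) -> list[GuideCandidate]:
    """Walk the SNP across guide positions and emit one candidate per offset.

    The default walk (length 22, offsets 2..13) yields a 12-candidate
    panel with the SNP sampled across seed and central positions.
    Offsets whose target window would fall off the sequence are skipped
    with a warning; an empty result is an error.
    """
    if guide_len < 15:
        raise GuideError(f"guide_len must be >= 15, got {guide_len}")
    lo, hi = snp_offset_range
    if lo > hi or lo < 1 or hi > guide_len:
        raise GuideError(f"invalid snp_offset_range {snp_offset_range} for guide_len {guide_len}")
    target = alleles.mut_cds.residues
    snp_pos = alleles.mutation.cds_position
    candidates: list[GuideCandidate] = []
    for idx, offset in enumerate(range(lo, hi + 1), start=1):
        end = snp_pos + offset - 1
        start = end - guide_len + 1
        if start < 1 or end > len(target):
            log.warning("snp_offset %d: window %d..%d outside sequence; skipped",
                        offset, start, end)
            continue
        window = target[start - 1 : end]
        candidates.append(
            GuideCandidate(
                name=f"{name_prefix}{idx}",
                guide_seq=revcomp(window),
                target_span=(start, end),
                snp_offset=offset,
            )
        )
    if not candidates:
        raise GuideError("no guide candidate could be placed on the target sequence")
    return candidates


@dataclass(frozen=True)
class MismatchRule:
    """Engineered selectivity mismatch: substitute ``base`` at guide
    ``position``. ``none()`` disables the substitution."""

    position: int | None = 14
    base: str = "A"

    @classmethod
    def none(cls) -> "MismatchRule":
        return cls(position=None)


def engineer_mismatch(guide: GuideCandidate, rule: MismatchRule = MismatchRule()) -> GuideCandidate:
    """Introduce the engineered mismatch (default: adenine at position 14).

    The substitution may not sit at the SNP-pairing position (it would
    destroy allele discrimination). If the guide already carries the
    substitute base there, the candidate is returned unchanged.
    """
    if rule.position is None:
        return guide
    L = len(guide)
    if not (1 <= rule.position <= L):
        raise GuideError(f"mismatch position {rule.position} outside guide 1..{L}")
    if rule.position == guide.snp_offset:
        raise GuideError(
            f"mismatch position {rule.position} equals snp_offset; would erase selectivity"
        )
    original = guide.guide_seq[rule.position - 1]
    if original == rule.base:
        log.info("guide %s already has %s at position %d; no mismatch introduced",
                 guide.name, rule.base, rule.position)
        return guide
    seq = list(guide.guide_seq)
    seq[rule.position - 1] = rule.base
    return replace(
        guide,
        guide_seq="".join(seq),
        engineered_mismatches=guide.engineered_mismatches + ((rule.position, rule.base),),
        engineered_originals=guide.engineered_originals + (original,),
    )


@dataclass(frozen=True)
class PositionWeightModel:
    """Per-position mismatch penalties by guide region.

    Heuristic defaults encode seed > central > supplementary mismatch
    impact; they are configuration, not science.
    """

    pos1: float = 0.05
    seed: float = 0.40
    central: float = 0.30
    supplementary: float = 0.10
    cap: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pos1, self.seed, self.central, self.supplementary) < 0 or self.cap <= 0:
            raise GuideError("weights must be >= 0 and cap > 0")

    def weight(self, position: int) -> float:
        if position == 1:
            return self.pos1
        if 2 <= position <= 8:
            return self.seed
        if 9 <= position <= 12:
            return self.central
        return self.supplementary


@dataclass(frozen=True)
class SilencingScore:
    potency_mut: float
    potency_wt: float
    potency_opt: float | None
    offtarget_hits: int = 0

    @property
    def selectivity_index(self) -> float:
        return self.potency_mut - self.potency_wt


def score_potency(guide: GuideCandidate | str, target_window: str,
                  model: PositionWeightModel = PositionWeightModel()) -> float:
    """Predicted silencing potency of a guide against one target window.

    ``potency = max(0, 1 - sum of mismatch weights / cap)``; perfect
    complementarity scores 1.0.
    """
    seq = guide.guide_seq if isinstance(guide, GuideCandidate) else guide
    penalty = sum(model.weight(p) for p in mismatch_positions(seq, target_window))
    return max(0.0, 1.0 - penalty / model.cap)


def score_selectivity(
    guide: GuideCandidate,
    alleles: AlleleSet,
    model: PositionWeightModel = PositionWeightModel(),
    transcriptome: list[NamedSequence] | None = None,
) -> SilencingScore:
    """Score a guide against the mutant, wild-type, and optimized windows.

    The optimized window is the homologous span on the optimized CDS
    (sequences are length-equal by construction); when the optimized CDS
    is absent its potency is reported as None, not zero.
    """
    start, end = guide.target_span
    mut_win = alleles.mut_cds.slice1(start, end)
    wt_win = alleles.wt_cds.slice1(start, end)
    pot_mut = score_potency(guide, mut_win, model)
    pot_wt = score_potency(guide, wt_win, model)
    pot_opt = None
    if alleles.opt_cds is not None:
        pot_opt = score_potency(guide, alleles.opt_cds.slice1(start, end), model)
    hits = len(offtarget_seed_scan(guide, transcriptome)) if transcriptome else 0
    return SilencingScore(pot_mut, pot_wt, pot_opt, offtarget_hits=hits)


def offtarget_seed_scan(
    guide: GuideCandidate, transcriptome: list[NamedSequence] | None
) -> list[tuple[str, int]]:
    """Find seed-complementary sites in mRNA-sense transcripts.

    Returns every (transcript id, 1-based position) where the transcript
    contains the reverse complement of the guide seed (positions 2-8).
    Overlapping occurrences are all reported.
    """
    if not transcriptome:
        return []
    site = revcomp(guide.seed)
    hits: list[tuple[str, int]] = []
    for tx in transcriptome:
        start = 0
        while True:
            i = tx.residues.find(site, start)
            if i == -1:
                break
            hits.append((tx.id, i + 1))
            start = i + 1
    return hits


def rank_candidates(
    scored: list[tuple[GuideCandidate, SilencingScore]]
) -> list[tuple[GuideCandidate, SilencingScore]]:
    """Deterministic ranking: selectivity desc, then fewer off-targets,
    then GC closest to 0.5, then lower snp_offset."""
    return sorted(
        scored,
        key=lambda cs: (
            -cs[1].selectivity_index,
            cs[1].offtarget_hits,
            abs(cs[0].gc_fraction - 0.5),
            cs[0].snp_offset,
        ),
    )


def candidate_table(
    scored: list[tuple[GuideCandidate, SilencingScore]]
) -> pd.DataFrame:
    """Ranked candidate report as a DataFrame (TSV-ready)."""
    rows = []
    for cand, score in rank_candidates(scored):
        rows.append(
            {
                "name": cand.name,
                "guide_seq": cand.guide_seq,
                "target_span": f"{cand.target_span[0]}..{cand.target_span[1]}",
                "snp_offset": cand.snp_offset,
                "mismatches": ";".join(f"{p}{b}" for p, b in cand.engineered_mismatches) or ".",
                "gc": round(cand.gc_fraction, 3),
                "potency_mut": round(score.potency_mut, 3),
                "potency_wt": round(score.potency_wt, 3),
                "potency_opt": None if score.potency_opt is None else round(score.potency_opt, 3),
                "selectivity": round(score.selectivity_index, 3),
                "offtargets": score.offtarget_hits,
            }
        )
    return pd.DataFrame(rows)
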