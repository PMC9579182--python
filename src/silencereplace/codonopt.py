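"""Silencing-resistant replacement CDS design by maximal codon divergence.

The replacement CDS must encode exactly the wild-type protein while
diverging from the wild-type (and hence mutant) nucleotide sequence as
much as synonymous recoding allows, so that allele-specific silencing
RNAs raised against the endogenous transcript cannot pair with it.

The optimizer is a deterministic greedy pass — each codon is replaced by
its most-distant synonymous codon above a usage floor — followed by a
repair pass that removes forbidden motifs (cloning sites, cryptic splice
donors, long homopolymers) and extreme GC windows by locally falling
back to next-most-divergent alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .guidewalk import GuideCandidate, mismatch_positions
from .seqcore import CodonTable, NamedSequence, SequenceError, revcomp, translate

log = logging.getLogger(__name__)

DEFAULT_FORBIDDEN_MOTIFS = (
    "CTGCAG",  # PstI, used for cassette cloning
    "AGATCT",  # BglII, used for cassette cloning
    "GGTAAG",  # canonical splice donor
    "AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT",  # homopolymers >= 6
)


class OptimizationError(ValueError):
    pass


@dataclass(frozen=True)
class OptimizationConstraints:
    """Knobs for the divergence-maximizing recoder.

    ``min_relative_codon_freq`` floors codon choice at a relative-usage
    threshold (0.10 by default: rare codons are avoided without giving
    up much divergence). ``gc_window`` is (window size, min fraction,
    max fraction). The stop codon is left untouched by default.
    """

    min_relative_codon_freq: float = 0.10
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN_MOTIFS
    gc_window: tuple[int, float, float] = (50, 0.25, 0.80)
    recode_stop: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_relative_codon_freq <= 1.0):
            raise OptimizationError("min_relative_codon_freq must be in [0, 1]")
        if any(not m for m in self.forbidden_motifs):
            raise OptimizationError("forbidden motifs must be non-empty strings")
        w, lo, hi = self.gc_window
        if w < 1 or not (0.0 <= lo <= hi <= 1.0):
            raise OptimizationError(f"invalid gc_window {self.gc_window}")


@dataclass(frozen=True)
class OptimizedCDS:
    """Recoded CDS with its divergence and motif-hygiene report."""

    dna: str
    identity_to_wt: float
    changed_positions: int
    motif_report: tuple[tuple[str, tuple[int, ...]], ...]  # motifs found pre-repair
    gc_warnings: tuple[int, ...] = ()  # window start positions still out of range
    repaired_codons: tuple[int, ...] = ()  # 1-based codon indices the repair pass modified

    def as_named(self, base_id: str) -> NamedSequence:
        return NamedSequence(
            f"{base_id}_opt",
            self.dna,
            description=f"codon-optimized, {100 * self.identity_to_wt:.1f}% identity to WT",
        )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise SequenceError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _ranked_synonyms(codon: str, table: CodonTable) -> list[str]:
    """Synonyms ordered by divergence preference: Hamming distance desc,
    relative usage desc, lexicographic. The input codon ranks by its own
    distance 0, i.e. last."""
    return sorted(
        table.synonyms(codon),
        key=lambda c: (-hamming(codon, c), -table.usage.get(c, 0.0), c),
    )


def max_divergent_codon(
    codon: str,
    table: CodonTable,
    constraints: OptimizationConstraints = OptimizationConstraints(),
) -> str:
    """Most-distant synonymous codon above the usage floor.

    Ties break by higher relative usage, then lexicographic order. If no
    synonym passes the floor, the unfiltered maximal-distance codon is
    returned with a warning.
    """
    codon = codon.upper()
    if table.amino_acid(codon) == "*":
        raise OptimizationError(f"{codon} is a stop codon; stop recoding is handled separately")
    ranked = _ranked_synonyms(codon, table)
    floor = constraints.min_relative_codon_freq
    passing = [c for c in ranked if table.usage.get(c, 0.0) >= floor]
    if passing:
        return passing[0]
    log.warning("no synonym of %s passes usage floor %.2f; using unfiltered choice", codon, floor)
    return ranked[0]


def _find_motifs(dna: str, motifs: tuple[str, ...]) -> list[tuple[str, int]]:
    """All (motif, 1-based position) occurrences, overlapping included."""
    found = []
    for motif in motifs:
        start = 0
        while True:
            i = dna.find(motif, start)
            if i == -1:
                break
            found.append((motif, i + 1))
            start = i + 1
    return found


def _gc_violations(dna: str, gc_window: tuple[int, float, float]) -> list[int]:
    """1-based start positions of windows whose GC is out of range."""
    w, lo, hi = gc_window
    if len(dna) < w:
        return []
    bad = []
    gc = sum(b in "GC" for b in dna[:w])
    for i in range(len(dna) - w + 1):
        if i > 0:
            gc += (dna[i + w - 1] in "GC") - (dna[i - 1] in "GC")
        frac = gc / w
        if not (lo <= frac <= hi):
            bad.append(i + 1)
    return bad


def optimize_cds(
    wt: NamedSequence,
    table: CodonTable | None = None,
    constraints: OptimizationConstraints = OptimizationConstraints(),
) -> OptimizedCDS:
    """Greedy maximal-divergence recoding with a motif/GC repair pass.

    Deterministic. The repair pass walks each forbidden-motif occurrence
    and swaps one overlapping codon for its next-ranked synonym; a motif
    that survives every alternative (forced by the protein sequence) is
    an error. GC-window violations are repaired best-effort and reported
    as warnings when they persist.
    """
    table = table or CodonTable.human()
    wt_protein = translate(wt.residues)  # validates the input CDS
    codons = [wt.residues[i : i + 3] for i in range(0, len(wt.residues), 3)]

    out: list[str] = []
    for codon in codons:
        if table.amino_acid(codon) == "*":
            if constraints.recode_stop:
                stops = sorted(table.synonyms(codon), key=lambda c: (-hamming(codon, c), c))
                out.append(stops[0])
            else:
                out.append(codon)
        else:
            out.append(max_divergent_codon(codon, table, constraints))

    # --- repair pass ---
    pre_repair = "".join(out)
    initial_motifs = _find_motifs(pre_repair, constraints.forbidden_motifs)
    greedy_choice = list(out)  # to report which codons the repair ends up changing

    def repair(check) -> bool:
        """Clear violations reported by `check` ((start, length) tuples,
        sorted); True when clean. Each step swaps one codon overlapping
        the first violation for its next-ranked synonym, reverting swaps
        that do not move the violation."""
        for _ in range(10 * len(codons) + 10):
            violations = check("".join(out))
            if not violations:
                return True
            span_start, span_len = violations[0]
            first = (span_start - 1) // 3
            last = min((span_start + span_len - 2) // 3, len(codons) - 1)
            progressed = False
            for ci in range(first, last + 1):
                if table.amino_acid(codons[ci]) == "*":
                    continue
                ranked = [
                    c for c in _ranked_synonyms(codons[ci], table)
                    if table.usage.get(c, 0.0) >= constraints.min_relative_codon_freq
                ] or _ranked_synonyms(codons[ci], table)
                current = out[ci]
                try:
                    alternatives = ranked[ranked.index(current) + 1 :]
                except ValueError:
                    alternatives = ranked
                for alt in alternatives:
                    out[ci] = alt
                    after = check("".join(out))
                    if not after or after[0] != (span_start, span_len):
                        progressed = True
                        break
                    out[ci] = current
                if progressed:
                    break
            if not progressed:
                return False
        return False

    def motif_check(dna: str):
        return sorted((pos, len(m)) for m, pos in _find_motifs(dna, constraints.forbidden_motifs))

    if not repair(motif_check):
        remaining = _find_motifs("".join(out), constraints.forbidden_motifs)
        raise OptimizationError(
            "irreparable forbidden motif(s) forced by the protein sequence: "
            + ", ".join(f"{m}@{p}" for m, p in remaining)
        )

    def gc_check(dna: str):
        return [(pos, constraints.gc_window[0]) for pos in _gc_violations(dna, constraints.gc_window)]

    snapshot = list(out)
    gc_clean = repair(gc_check)
    if _find_motifs("".join(out), constraints.forbidden_motifs):
        # GC repair must never reintroduce a motif; roll it back entirely
        out[:] = snapshot
        gc_clean = False
    final = "".join(out)
    gc_left = () if gc_clean else tuple(_gc_violations(final, constraints.gc_window))
    if gc_left:
        log.warning("GC windows still out of range at %d position(s)", len(gc_left))

    if translate(final) != wt_protein:
        raise OptimizationError("internal error: recoded CDS changed the protein")

    ident = sum(a == b for a, b in zip(wt.residues, final)) / len(final)
    motif_map: dict[str, list[int]] = {}
    for m, p in initial_motifs:
        motif_map.setdefault(m, []).append(p)
    return OptimizedCDS(
        dna=final,
        identity_to_wt=ident,
        changed_positions=hamming(wt.residues, final),
        motif_report=tuple((m, tuple(ps)) for m, ps in sorted(motif_map.items())),
        gc_warnings=gc_left,
        repaired_codons=tuple(
            i + 1 for i, (a, b) in enumerate(zip(greedy_choice, out)) if a != b
        ),
    )


# ---------------------------------------------------------------------------
# escape verification

@dataclass(frozen=True)
class EscapeEntry:
    guide_name: str
    min_mismatches: int
    worst_window_start: int  # 1-based, on the optimized CDS
    seed_match: bool
    passed: bool


@dataclass(frozen=True)
class EscapeReport:
    entries: tuple[EscapeEntry, ...]

    @property
    def overall_pass(self) -> bool:
        return all(e.passed for e in self.entries)


def verify_escape(
    opt_dna: str,
    guides: list[GuideCandidate],
    min_mismatches: int = 4,
) -> EscapeReport:
    """Check that no guide can still pair with the recoded CDS.

    For each guide, every window of the optimized CDS is compared with
    the guide's perfect-match target (its reverse complement); the guide
    escapes when the minimum mismatch count over all windows reaches
    ``min_mismatches`` or when no perfect seed-complementary site exists.
    Report-only: failures are flagged, not raised.
    """
    if min_mismatches < 1:
        raise OptimizationError("min_mismatches must be >= 1")
    entries = []
    for guide in guides:
        L = len(guide)
        if L > len(opt_dna):
            entries.append(EscapeEntry(guide.name, L, 1, False, True))
            continue
        best, best_start = L + 1, 1
        for i in range(len(opt_dna) - L + 1):
            mm = len(mismatch_positions(guide.guide_seq, opt_dna[i : i + L]))
            if mm < best:
                best, best_start = mm, i + 1
        seed_site = revcomp(guide.seed)
        seed_hit = seed_site in opt_dna
        entries.append(
            EscapeEntry(
                guide.name,
                best,
                best_start,
                seed_hit,
                passed=(best >= min_mismatches) or (not seed_hit),
            )
        )
    return EscapeReport(tuple(entries))
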