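"""Point mutations in HGVS coding notation and WT/mutant/optimized allele sets.

A :class:`PointMutation` is a single-nucleotide substitution located by
its 1-based position within the CDS (``c.`` convention: position 1 is
the A of the start ATG). An :class:`AlleleSet` ties together the
wild-type CDS, the mutant CDS derived from it, and optionally a
codon-optimized, silencing-resistant replacement CDS encoding the same
protein as wild type.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .seqcore import NamedSequence, SequenceError, translate

log = logging.getLogger(__name__)

_HGVS_C = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


class MutationError(ValueError):
    """Unparseable or inapplicable point mutation."""


@dataclass(frozen=True)
class PointMutation:
    """A single-base substitution at a 1-based CDS position."""

    cds_position: int
    ref_base: str
    alt_base: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise MutationError(f"cds_position must be >= 1, got {self.cds_position}")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT" or len(b) != 1:
                raise MutationError(f"mutation bases must be single DNA bases, got {b!r}")
        if self.ref_base == self.alt_base:
            raise MutationError("ref and alt base are identical")
        if not self.label:
            object.__setattr__(
                self, "label", f"c.{self.cds_position}{self.ref_base}>{self.alt_base}"
            )

    @classmethod
    def parse(cls, text: str) -> "PointMutation":
        """Parse ``c.<pos><ref>><alt>`` notation, e.g. ``c.617G>A``."""
        m = _HGVS_C.match(text.strip())
        if not m:
            raise MutationError(
                f"cannot parse mutation {text!r}; expected c.<pos><ref>><alt> like c.617G>A"
            )
        return cls(int(m.group(1)), m.group(2), m.group(3), label=text.strip())

    @property
    def codon_index(self) -> int:
        """1-based index of the affected codon (c.617 -> codon 206)."""
        return (self.cds_position - 1) // 3 + 1

    @property
    def offset_in_codon(self) -> int:
        """Position of the substitution within its codon, in {1, 2, 3}."""
        return (self.cds_position - 1) % 3 + 1

    def inverse(self) -> "PointMutation":
        return PointMutation(self.cds_position, self.alt_base, self.ref_base)


def apply_point_mutation(cds: NamedSequence, mutation: PointMutation) -> NamedSequence:
    """Return the CDS with the substitution applied.

    The reference base is checked against the sequence first; a mismatch
    is an error (it almost always means a wrong transcript or an
    off-by-one coordinate).
    """
    pos = mutation.cds_position
    if pos > len(cds):
        raise MutationError(
            f"position {pos} beyond CDS {cds.id!r} of length {len(cds)}"
        )
    found = cds.residues[pos - 1]
    if found != mutation.ref_base:
        raise MutationError(
            f"reference mismatch at c.{pos} of {cds.id!r}: "
            f"expected {mutation.ref_base}, found {found}"
        )
    mutated = cds.residues[: pos - 1] + mutation.alt_base + cds.residues[pos:]
    return NamedSequence(
        f"{cds.id}_mut", mutated, description=f"{cds.description} {mutation.label}".strip()
    )


@dataclass(frozen=True)
class AlleleSet:
    """Wild-type / mutant / (optional) codon-optimized CDS triplet.

    Invariants enforced at construction: wt and mut are length-equal and
    differ exactly at the mutation position; when the optimized CDS is
    present it translates identically to wild type.

    ``mrna_context`` optionally carries a longer transcript sequence in
    which the CDS starts at ``cds_offset`` (0-based), letting guide
    windows extend into UTRs; design defaults keep this off.
    """

    wt_cds: NamedSequence
    mut_cds: NamedSequence
    mutation: PointMutation
    opt_cds: NamedSequence | None = None
    mrna_context: NamedSequence | None = None
    cds_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.wt_cds) != len(self.mut_cds):
            raise SequenceError("wt and mut CDS must have equal length")
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.wt_cds.residues, self.mut_cds.residues))
            if a != b
        ]
        if diffs != [self.mutation.cds_position]:
            raise SequenceError(
                f"wt/mut differ at positions {diffs}, expected exactly "
                f"[{self.mutation.cds_position}]"
            )
        if self.opt_cds is not None and translate(self.opt_cds.residues) != translate(
            self.wt_cds.residues
        ):
            raise SequenceError(
                "optimized CDS does not encode the wild-type protein"
            )

    @property
    def identity_opt_to_wt(self) -> float | None:
        """Positional nucleotide identity of the optimized CDS to WT."""
        if self.opt_cds is None:
            return None
        wt, opt = self.wt_cds.residues, self.opt_cds.residues
        if len(wt) != len(opt):
            raise SequenceError("identity is positional; lengths must match")
        return sum(a == b for a, b in zip(wt, opt)) / len(wt)


def build_allele_set(
    wt: NamedSequence,
    mutation: PointMutation,
    opt: NamedSequence | None = None,
    mrna_context: NamedSequence | None = None,
    cds_offset: int = 0,
) -> AlleleSet:
    """Derive the mutant CDS and assemble a validated allele set.

    A synonymous mutation (identical proteins) is allowed with a logged
    warning; an optimized CDS with a different protein is an error.
    """
    mut = apply_point_mutation(wt, mutation)
    wt_protein = translate(wt.residues)
    mut_protein = translate(mut.residues, allow_internal_stop=True)
    if wt_protein == mut_protein:
        log.warning("mutation %s is synonymous: wt and mutant proteins are identical",
                    mutation.label)
    alleles = AlleleSet(
        wt_cds=wt,
        mut_cds=mut,
        mutation=mutation,
        opt_cds=opt,
        mrna_context=mrna_context,
        cds_offset=cds_offset,
    )
    if opt is not None and alleles.identity_opt_to_wt is not None:
        log.info("optimized CDS identity to WT: %.1f%%", 100 * alleles.identity_opt_to_wt)
    return alleles
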