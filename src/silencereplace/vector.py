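"""AAV vector genome assembly, exact size accounting, packaging audit.

A vector genome is the ordered ITR-to-ITR element list that gets
packaged into the capsid. Single-stranded AAV packages ~4.7 kb
(ITRs included); self-complementary genomes replicate as dimers and
effectively halve that budget. Elements may carry a sequence or, when
only the length is known (e.g. a proprietary intron), a declared
length; length-only genomes can still be audited and emitted as
GenBank with N-fill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from . import seqcore

log = logging.getLogger(__name__)

ELEMENT_KINDS = (
    "ITR", "enhancer", "promoter", "intron", "amiR_cassette",
    "cds", "reporter", "polyA", "linker",
)

DEFAULT_PACKAGING_LIMITS = {"single_stranded": 4700, "self_complementary": 2400}


class VectorError(ValueError):
    pass


@dataclass(frozen=True)
class VectorElement:
    name: str
    kind: str
    sequence: str | None = None
    declared_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise VectorError(f"unknown element kind {self.kind!r}; expected one of {ELEMENT_KINDS}")
        if self.sequence is None and self.declared_length is None:
            raise VectorError(f"element {self.name!r} needs a sequence or a declared length")
        if self.sequence is not None:
            object.__setattr__(self, "sequence", self.sequence.upper())
            if self.declared_length is not None and self.declared_length != len(self.sequence):
                raise VectorError(
                    f"element {self.name!r}: declared length {self.declared_length} != "
                    f"sequence length {len(self.sequence)}"
                )
        if self.length < 1:
            raise VectorError(f"element {self.name!r} has length < 1")

    @property
    def length(self) -> int:
        return len(self.sequence) if self.sequence is not None else self.declared_length


@dataclass(frozen=True)
class VectorGenome:
    name: str
    elements: tuple[VectorElement, ...]
    genome_type: Literal["single_stranded", "self_complementary"]
    packaging_limit: int

    @property
    def total_length(self) -> int:
        return sum(e.length for e in self.elements)

    @property
    def verdict(self) -> str:
        return "fits" if self.total_length <= self.packaging_limit else "exceeds"

    @property
    def spans(self) -> list[tuple[str, int, int]]:
        """(name, start, end) per element, 1-based inclusive, consecutive."""
        out, pos = [], 1
        for e in self.elements:
            out.append((e.name, pos, pos + e.length - 1))
            pos += e.length
        return out


def assemble_vector(
    elements: Sequence[VectorElement],
    genome_type: Literal["single_stranded", "self_complementary"] = "single_stranded",
    name: str = "vector",
    packaging_limit: int | None = None,
) -> VectorGenome:
    """Assemble and audit a vector genome.

    Structural rules: first and last elements are ITRs, exactly one
    promoter, at most one intron. A genome over the packaging limit is
    reported with verdict ``exceeds`` and a warning — not an error, so
    oversized layouts can still be compared.
    """
    if len(elements) < 2 or elements[0].kind != "ITR" or elements[-1].kind != "ITR":
        raise VectorError("genome must start and end with an ITR")
    n_promoters = sum(e.kind == "promoter" for e in elements)
    if n_promoters != 1:
        raise VectorError(f"genome must contain exactly one promoter, found {n_promoters}")
    if sum(e.kind == "intron" for e in elements) > 1:
        raise VectorError("genome may contain at most one intron")
    if packaging_limit is None:
        packaging_limit = DEFAULT_PACKAGING_LIMITS[genome_type]
    genome = VectorGenome(name, tuple(elements), genome_type, packaging_limit)
    if genome.verdict == "exceeds":
        log.warning(
            "genome %s: %d nt exceeds the %d nt packaging limit",
            name, genome.total_length, packaging_limit,
        )
    return genome


def compare_layouts(genomes: Sequence[VectorGenome]) -> pd.DataFrame:
    """Size comparison table: name, total length, delta vs the smallest,
    verdict; sorted ascending by length (ties by name) — deterministic
    under input permutation."""
    if len(genomes) < 2:
        raise VectorError("compare_layouts needs at least two genomes")
    rows = sorted(
        ({"name": g.name, "total_length": g.total_length, "verdict": g.verdict}
         for g in genomes),
        key=lambda r: (r["total_length"], r["name"]),
    )
    smallest = rows[0]["total_length"]
    for r in rows:
        r["delta_vs_smallest"] = r["total_length"] - smallest
    return pd.DataFrame(rows, columns=["name", "total_length", "delta_vs_smallest", "verdict"])


def write_genbank(genome: VectorGenome, path) -> None:
    seqcore.write_genbank(genome, path)


def write_fasta(genome: VectorGenome, path) -> None:
    """Emit the genome sequence as FASTA; length-only elements make the
    genome non-emittable (use GenBank, which N-fills)."""
    missing = [e.name for e in genome.elements if e.sequence is None]
    if missing:
        raise VectorError(
            f"cannot emit FASTA: elements without sequence: {missing}; use GenBank"
        )
    seq = "".join(e.sequence for e in genome.elements)
    seqcore.write_fasta(
        [seqcore.NamedSequence(genome.name, seq, description=f"{genome.genome_type} AAV genome")],
        path,
    )
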