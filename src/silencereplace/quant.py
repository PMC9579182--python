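"""Mutant vs wild-type allele counting in SNP-spanning amplicon reads.

Amplicon reads fully cover the SNP by design, so no alignment is
needed: each allele is recognized by an exact diagnostic k-mer — the
SNP base flanked by ``anchor_len`` bases on each side (length
``2 * anchor_len + 1``) — searched in both orientations. A read counts
for an allele when it contains exactly one allele's k-mer and the SNP
base passes the quality floor; everything else is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .alleles import AlleleSet
from .seqcore import FastqRead, read_fastq, revcomp


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleCountResult:
    n_mut: int
    n_wt: int
    n_ambiguous: int

    @property
    def n_classified(self) -> int:
        return self.n_mut + self.n_wt

    @property
    def frac_mut(self) -> float | None:
        """Mutant fraction of classified reads; None when nothing classified."""
        return self.n_mut / self.n_classified if self.n_classified else None

    @property
    def frac_wt(self) -> float | None:
        return self.n_wt / self.n_classified if self.n_classified else None

    def as_dict(self) -> dict:
        return {
            "n_mut": self.n_mut,
            "n_wt": self.n_wt,
            "n_ambiguous": self.n_ambiguous,
            "frac_mut": self.frac_mut,
            "frac_wt": self.frac_wt,
        }


def diagnostic_kmers(alleles: AlleleSet, anchor_len: int) -> tuple[str, str]:
    """(mutant k-mer, WT k-mer) centred on the SNP; each must occur
    exactly once in its own CDS, else a larger anchor is required."""
    if anchor_len < 5:
        raise QuantError(f"anchor_len must be >= 5, got {anchor_len}")
    pos = alleles.mutation.cds_position
    lo, hi = pos - anchor_len, pos + anchor_len
    if lo < 1 or hi > len(alleles.mut_cds):
        raise QuantError(
            f"anchor_len {anchor_len} extends beyond the CDS around position {pos}"
        )
    kmers = (alleles.mut_cds.slice1(lo, hi), alleles.wt_cds.slice1(lo, hi))
    for kmer, cds in zip(kmers, (alleles.mut_cds, alleles.wt_cds)):
        if cds.residues.count(kmer) != 1:
            raise QuantError(
                f"diagnostic k-mer {kmer} is not unique in {cds.id!r}; "
                "increase anchor_len"
            )
    return kmers


def _classify(read: FastqRead, kmer: str, anchor_len: int, min_qual: int) -> bool:
    """True iff the read contains the k-mer (either orientation) with
    adequate quality at the SNP base."""
    i = read.seq.find(kmer)
    if i != -1:
        return read.quals[i + anchor_len] >= min_qual
    i = read.seq.find(revcomp(kmer))
    if i != -1:
        return read.quals[i + anchor_len] >= min_qual
    return False


def count_alleles(
    reads: Iterable[FastqRead] | str | Path,
    alleles: AlleleSet,
    anchor_len: int = 10,
    min_base_qual: int = 20,
) -> AlleleCountResult:
    """Classify SNP-spanning amplicon reads as mutant, WT, or ambiguous.

    ``reads`` may be an iterable of reads or a FASTQ path (gzip
    transparent). Reads matching neither or both diagnostic k-mers, or
    failing the SNP base-quality floor, are ambiguous. Fractions are
    computed over classified reads only.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    mut_kmer, wt_kmer = diagnostic_kmers(alleles, anchor_len)
    n_mut = n_wt = n_amb = 0
    for read in reads:
        is_mut = _classify(read, mut_kmer, anchor_len, min_base_qual)
        is_wt = _classify(read, wt_kmer, anchor_len, min_base_qual)
        if is_mut and not is_wt:
            n_mut += 1
        elif is_wt and not is_mut:
            n_wt += 1
        else:
            n_amb += 1
    return AlleleCountResult(n_mut, n_wt, n_amb)
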