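"""Seeded fixture generators: toy allele sets, decoy transcriptomes,
synthetic introns, a receptor-like full-length CDS, and amplicon read
simulation.

Everything here is deterministic for a fixed seed (one
``numpy.random.Generator`` per call, no global state), so every module
of the package is testable without downloading reference data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._codon_usage import HUMAN_CODON_FRACTIONS
from .alleles import AlleleSet, PointMutation, build_allele_set
from .seqcore import FastqRead, NamedSequence, STOP_CODONS, revcomp, translate

_BASES = "ACGT"
_NON_STOP_CODONS = sorted(
    c for c in HUMAN_CODON_FRACTIONS if c not in STOP_CODONS
)
_CODON_WEIGHTS = np.array([HUMAN_CODON_FRACTIONS[c] for c in _NON_STOP_CODONS])
_CODON_WEIGHTS = _CODON_WEIGHTS / _CODON_WEIGHTS.sum()


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults emulate the package's exemplar use case: a ~300 nt toy CDS
    with a mid-sequence missense SNP, a small decoy transcriptome, and
    SNP-centred amplicon reads with a 1% substitution error rate at the
    mutant fraction observed in untreated patient-derived cells (0.654).
    """

    seed: int = 0
    cds_length: int = 300  # multiple of 3, incl. stop codon
    snp_codon: int = 34  # 1-based codon index of the SNP
    snp_offset_in_codon: int = 2  # 1..3
    n_transcripts: int = 10
    transcript_length: int = 500
    n_reads: int = 5000
    mut_fraction: float = 0.654
    error_rate: float = 0.01
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.cds_length % 3 or self.cds_length < 60:
            raise SimulationError("cds_length must be a multiple of 3 and >= 60")
        if not (1 < self.snp_codon < self.cds_length // 3):
            raise SimulationError("snp_codon must be an internal (non-start, non-stop) codon")
        if not (0.0 <= self.mut_fraction <= 1.0):
            raise SimulationError("mut_fraction must be in [0, 1]")
        if not (0.0 <= self.error_rate <= 0.1):
            raise SimulationError("error_rate must be in [0, 0.1]")


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + human-usage-weighted non-stop codons + one stop (TAA)."""
    body = rng.choice(_NON_STOP_CODONS, size=n_codons - 2, p=_CODON_WEIGHTS)
    return "ATG" + "".join(body) + "TAA"


def make_toy_allele_set(config: SimulationConfig = SimulationConfig()) -> AlleleSet:
    """Random ORF with a missense SNP injected at the configured codon.

    If the configured substitution would be synonymous or create a stop
    codon, alternative alt bases (then positions within the codon) are
    tried deterministically until a missense change is found.
    """
    rng = np.random.default_rng(config.seed)
    n_codons = config.cds_length // 3
    wt = _random_orf(rng, n_codons)
    wt_protein = translate(wt)

    for offset in [config.snp_offset_in_codon] + [
        o for o in (1, 2, 3) if o != config.snp_offset_in_codon
    ]:
        pos = (config.snp_codon - 1) * 3 + offset  # 1-based CDS position
        ref = wt[pos - 1]
        for alt in [b for b in _BASES if b != ref]:
            mutated_codon = list(wt[(config.snp_codon - 1) * 3 : config.snp_codon * 3])
            mutated_codon[offset - 1] = alt
            codon = "".join(mutated_codon)
            if codon in STOP_CODONS:
                continue
            if translate(codon) == wt_protein[config.snp_codon - 1]:
                continue  # synonymous
            mutation = PointMutation(pos, ref, alt)
            return build_allele_set(
                NamedSequence("toyWT", wt, description=f"synthetic ORF seed={config.seed}"),
                mutation,
            )
    raise SimulationError(
        f"no missense substitution possible at codon {config.snp_codon}"
    )


def make_decoy_transcriptome(config: SimulationConfig = SimulationConfig()) -> list[NamedSequence]:
    """Random mRNA-sense decoy transcripts for off-target scanning."""
    rng = np.random.default_rng(config.seed + 1)
    out = []
    for i in range(config.n_transcripts):
        seq = "".join(rng.choice(list(_BASES), size=config.transcript_length))
        out.append(NamedSequence(f"decoy{i + 1}", seq, description="synthetic decoy transcript"))
    return out


def make_intron(length: int = 172, seed: int = 0) -> NamedSequence:
    """Synthetic intron with canonical GT...AG boundaries."""
    if length < 10:
        raise SimulationError("intron length must be >= 10")
    rng = np.random.default_rng(seed)
    middle = "".join(rng.choice(list(_BASES), size=length - 4))
    return NamedSequence(f"syn_intron_{length}", "GT" + middle + "AG",
                         description=f"synthetic {length} nt intron")


def make_receptor_like_cds(seed: int = 206) -> tuple[NamedSequence, PointMutation]:
    """Synthetic stand-in for a full-length type-I receptor CDS.

    509 codons plus stop (1530 nt) sampled from human codon usage, with
    codon 206 fixed to CGC (Arg) so that the exemplar c.617G>A missense
    substitution (Arg206His) applies. This is a synthetic fixture — it
    matches the real receptor CDS in length, composition statistics and
    mutation context, not in sequence.
    """
    rng = np.random.default_rng(seed)
    n_codons = 510  # 509 residues + stop
    codons = ["ATG"] + list(rng.choice(_NON_STOP_CODONS, size=n_codons - 2, p=_CODON_WEIGHTS))
    codons[205] = "CGC"  # codon 206; c.617 is its second base
    cds = "".join(codons) + "TAA"
    mutation = PointMutation(617, "G", "A", label="c.617G>A")
    return (
        NamedSequence("receptorWT_synthetic", cds,
                      description="synthetic receptor-like CDS (509 aa + stop)"),
        mutation,
    )


def phred_for_error_rate(e: float) -> int:
    """Constant per-base quality consistent with substitution rate e."""
    if e <= 0:
        return 40
    return min(40, max(2, round(-10 * math.log10(e))))


def simulate_amplicon_reads(
    alleles: AlleleSet, config: SimulationConfig = SimulationConfig()
) -> list[FastqRead]:
    """Simulate SNP-spanning amplicon reads from a two-allele mixture.

    Each read is the SNP-centred amplicon window from the mutant allele
    with probability ``mut_fraction`` (else wild type), with i.i.d.
    substitution errors at ``error_rate`` and a 50% chance of being
    reverse-complemented. Base qualities encode the error rate.
    """
    rng = np.random.default_rng(config.seed + 2)
    L = config.read_length
    snp = alleles.mutation.cds_position
    start = max(1, min(snp - L // 2, len(alleles.wt_cds) - L + 1))
    end = start + L - 1
    if not (start <= snp <= end):
        raise SimulationError("read window does not cover the SNP")
    templates = {
        True: alleles.mut_cds.slice1(start, end),
        False: alleles.wt_cds.slice1(start, end),
    }
    qual = phred_for_error_rate(config.error_rate)
    quals = tuple([qual] * L)
    reads = []
    is_mut = rng.random(config.n_reads) < config.mut_fraction
    do_rc = rng.random(config.n_reads) < 0.5
    for i in range(config.n_reads):
        seq = list(templates[bool(is_mut[i])])
        if config.error_rate > 0:
            err_mask = rng.random(L) < config.error_rate
            for j in np.nonzero(err_mask)[0]:
                seq[j] = rng.choice([b for b in _BASES if b != seq[j]])
        read = "".join(seq)
        if do_rc[i]:
            read = revcomp(read)
        reads.append(FastqRead(f"read{i + 1}", read, quals))
    return reads
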