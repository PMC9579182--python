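"""Human codon-fraction table (fraction of each amino acid's usage).

Values are the widely tabulated human codon fractions (per amino-acid
family, summing to ~1 within each family). The package rescales them
within each family so the most-used synonymous codon gets relative
usage 1.0; see :class:`silencereplace.seqcore.CodonTable`.
"""

HUMAN_CODON_FRACTIONS: dict[str, float] = {
    # Phe
    "TTT": 0.46, "TTC": 0.54,
    # Leu
    "TTA": 0.08, "TTG": 0.13, "CTT": 0.13, "CTC": 0.20, "CTA": 0.07, "CTG": 0.40,
    # Ile
    "ATT": 0.36, "ATC": 0.47, "ATA": 0.17,
    # Met
    "ATG": 1.00,
    # Val
    "GTT": 0.18, "GTC": 0.24, "GTA": 0.12, "GTG": 0.46,
    # Ser
    "TCT": 0.19, "TCC": 0.22, "TCA": 0.15, "TCG": 0.05, "AGT": 0.15, "AGC": 0.24,
    # Pro
    "CCT": 0.29, "CCC": 0.32, "CCA": 0.28, "CCG": 0.11,
    # Thr
    "ACT": 0.25, "ACC": 0.36, "ACA": 0.28, "ACG": 0.11,
    # Ala
    "GCT": 0.27, "GCC": 0.40, "GCA": 0.23, "GCG": 0.11,
    # Tyr
    "TAT": 0.44, "TAC": 0.56,
    # stop
    "TAA": 0.30, "TAG": 0.24, "TGA": 0.47,
    # His
    "CAT": 0.42, "CAC": 0.58,
    # Gln
    "CAA": 0.27, "CAG": 0.73,
    # Asn
    "AAT": 0.47, "AAC": 0.53,
    # Lys
    "AAA": 0.43, "AAG": 0.57,
    # Asp
    "GAT": 0.46, "GAC": 0.54,
    # Glu
    "GAA": 0.42, "GAG": 0.58,
    # Cys
    "TGT": 0.46, "TGC": 0.54,
    # Trp
    "TGG": 1.00,
    # Arg
    "CGT": 0.08, "CGC": 0.18, "CGA": 0.11, "CGG": 0.20, "AGA": 0.21, "AGG": 0.21,
    # Gly
    "GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25,
}
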