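# silencereplace

Design toolkit for **allele-specific "silence-and-replace" gene therapy
constructs** built around a single pathogenic point mutation. The
exemplar application is fibrodysplasia ossificans progressiva (FOP),
caused by the recurrent activating *ACVR1* c.617G>A (p.R206H)
substitution: the therapeutic concept silences the mutant transcript
with an allele-specific artificial miRNA (amiR) while co-expressing a
recoded, silencing-resistant wild-type replacement cDNA from the same
AAV vector.

The package is for molecular biologists and vector engineers who need
to go from *a wild-type CDS plus a point mutation in HGVS `c.`
notation* to a complete, size-audited AAV construct design:

1. **Guide walk** (`guidewalk`) — tile antisense guides so the SNP
   occupies successive guide positions (default: 22-nt guides, SNP at
   positions 2–13, a 12-candidate panel). Each guide is the exact
   reverse complement of its mutant target window; an engineered
   adenine mismatch (default guide position 14) sharpens allele
   selectivity. Guides are scored with a position-weighted mismatch
   model (seed ≫ central ≫ supplementary) giving a potency in [0, 1]
   per allele and a selectivity index
   `potency_mut − potency_wt ∈ [−1, 1]`, plus a seed-complement
   (positions 2–8) off-target scan of an optional transcriptome.
2. **Replacement CDS** (`codonopt`) — protein-preserving recoding that
   *maximizes* nucleotide divergence: every codon is swapped for its
   most-distant synonymous codon above a relative-usage floor (0.10 on
   the bundled human table), then a repair pass removes forbidden
   motifs (PstI `CTGCAG`, BglII `AGATCT`, splice donor `GGTAAG`,
   homopolymers ≥ 6) and extreme GC windows. `verify_escape` proves no
   panel guide can still pair with the recoded CDS.
3. **Cassette & vector** (`scaffold`, `vector`) — embed the guide in a
   miR-33-style pri-amiR hairpin (PstI site, 5' flank, passenger with
   bulges, loop, guide, 3' flank, BglII site), insert it mid-intron
   away from splice sites, and assemble an annotated ITR-to-ITR AAV
   genome with exact size accounting against the ~4.7 kb
   single-stranded packaging limit (2.4 kb self-complementary).
4. **Screening & readout** (`silencing`, `quant`) — generate
   dual-luciferase sensor inserts (allele target sites in the RLuc
   3'UTR; silencing read as RLuc/FLuc vs control) and count mutant vs
   wild-type alleles in SNP-spanning amplicon reads by exact
   diagnostic k-mer matching.
5. **Fixtures** (`synth`) — seeded generators for toy allele sets,
   decoy transcriptomes, synthetic introns, a full-length
   receptor-like CDS, and simulated amplicon reads, so the entire
   pipeline runs and is tested without any downloads.

## Worked example

```sh
silence-replace synth alleles --seed 1 -o toy.fa   # toy WT CDS (300 nt)
silence-replace design toy.fa 'c.101C>A' -o run1
```

prints

```
amiR-RH7 selected; optimized CDS identity 62.0%; vector 1687 nt (fits); outputs in run1
```

meaning: of the 12-guide walk panel, `amiR-RH7` (SNP at guide position
8) ranked best by selectivity; the divergence-maximized replacement
CDS retains only 62.0% nucleotide identity to wild type while encoding
the identical protein; and the assembled single-stranded AAV genome —
ITRs, CMV enhancer/CBA promoter, the amiR-loaded 172-nt synthetic
intron, the replacement CDS, and polyA — totals 1687 nt, comfortably
inside the 4700-nt packaging limit. `run1/` contains the ranked
candidate table (`candidates.tsv`), the escape report (`escape.tsv`),
the cassette and replacement-CDS FASTA files, the annotated vector
GenBank file, and a `manifest.json` with the effective configuration
and input checksums. Re-running the same command reproduces every
output byte for byte.

The same steps are available as library calls (`enumerate_guides`,
`optimize_cds`, `build_cassette`, `assemble_vector`, `count_alleles`,
…) on plain in-memory objects; see the module docstrings.

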