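# Methods

This note documents the models, defaults, and design decisions behind
the package, and what the synthetic fixtures do and do not establish.

## Coordinate and pairing conventions

Internally all coordinates are 0-based half-open; everything
user-facing (HGVS `c.` positions, target spans, GenBank features) is
1-based inclusive. A `c.` position counts from the A of the start ATG,
so c.617 falls at offset 2 of codon 206 (`floor((617−1)/3)+1`). Only
single-nucleotide substitutions are supported: the design procedure is
defined around discriminating one SNP, and indels would change every
downstream window. `N` is accepted in sequencing reads but rejected in
design inputs, which must be unambiguous.

Guides are stored 5'→3' in antisense orientation. Guide position *i*
pairs with target position `span.end − i + 1`; equivalently a guide
with no engineered mismatch is the exact reverse complement of its
mutant target window. This invariant is property-tested across
hundreds of seeded fixtures and is the anchor for everything
downstream (cassette guide feature, sensor inserts, escape scanning).

## Sequence walk and selectivity model

The walk emits one candidate per SNP offset. Defaults: guide length
22 nt, offsets 2–13, i.e. a 12-candidate panel that samples the SNP
across the seed (2–8) and central (9–12) regions — the offsets where
single-nucleotide discrimination is strongest. Both are configurable;
windows that would run off the transcript are skipped with a warning.

The engineered selectivity mismatch substitutes adenine at guide
position 14 by default. The substituted base is part of the published
design idea; its position is our choice: position 14 lies in the
supplementary region, outside the seed, and is never allowed to
coincide with the SNP offset (that would erase discrimination). If the
guide already carries the substitute base there, the candidate is
returned unchanged.

Potency of a guide against a window is a heuristic position-weighted
mismatch penalty:

    potency = max(0, 1 − Σ_{mismatched p} w(p) / cap)

with default weights w(1) = 0.05, w(seed 2–8) = 0.40,
w(central 9–12) = 0.30, w(supplementary 13–L) = 0.10 and cap 1.0.
These weights are *configuration, not science*: they encode the
qualitative ordering seed ≫ central ≫ supplementary known from RNAi
target recognition, chosen so that a lone seed mismatch (the SNP seen
from the wild-type allele) costs 0.40 of potency. The selectivity
index is `potency_mut − potency_wt`; under any all-positive weight
model every SNP-covering guide has selectivity > 0, which is
property-tested. Candidate ranking breaks selectivity ties by fewer
seed off-target hits, then GC fraction closest to 0.5, then lower SNP
offset — a deterministic ordering, not a claim about biology.

The off-target scan reports exact matches of the reverse complement of
the guide seed (positions 2–8) in mRNA-sense transcripts. It is a
conservative screen: thermodynamics, expression levels and 3'UTR
context are out of scope.

## Replacement CDS optimization

The objective is maximal nucleotide divergence under exact protein
preservation — the replacement transcript must escape the very guides
designed here, so unlike expression-oriented codon optimizers we
*minimize* identity. Each codon is replaced by the synonymous codon at
maximal Hamming distance whose relative usage (bundled human codon
fractions, rescaled so each family's most-used codon is 1.0) is at
least 0.10; ties break by higher usage, then lexicographically. The
floor avoids rare codons at almost no cost in divergence; if nothing
passes the floor the unfiltered most-distant codon is used with a
warning. The stop codon is left unchanged by default (no silencing
target spans it).

A deterministic repair pass then rescans for forbidden motifs —
defaults: the PstI/BglII cloning sites used for cassette insertion, the
canonical splice-donor `GGTAAG`, homopolymers of length ≥ 6 — and GC
windows outside 0.25–0.80 per 50 nt, swapping one codon overlapping the
first violation for its next-ranked synonym (reverting swaps that do
not move the violation) until clean. A motif forced by the protein
sequence is an error; GC violations are repaired best-effort and
reported as warnings, and GC repair is rolled back entirely if it would
reintroduce a motif. The result records exactly which codons repair
touched, so tests can verify that everywhere else the output equals an
exhaustive per-codon brute force.

Greedy-per-codon plus local repair was chosen over global optimization
deliberately: the objective decomposes per codon except for the rare
window constraints, and determinism and auditability matter more here
than squeezing out the last percent of divergence. On human-usage-
typical full-length CDSs the procedure lands near 60–64% identity,
well below the ~74% reported for commercial optimizers with weaker
objectives — which is the point: the published figure is treated as an
upper bound for this stronger objective, not an equality.

`verify_escape` scans every window of the recoded CDS against each
guide's perfect-match target and reports the minimum mismatch count
(default pass threshold: ≥ 4 mismatches, or no perfect
seed-complementary site at all). It is report-only; a planted perfect
target window is the tested positive control.

## Cassette and vector assembly

Cassette layout: PstI site + 5' flank + passenger + loop + guide +
3' flank + BglII site. The passenger is the reverse complement of the
guide with declared bulge positions broken by setting the passenger
base equal to the guide base at the aligned position — in DNA this
always destroys Watson–Crick pairing. Default bulges sit at aligned
guide positions 11–12, a common strategy to bias guide-strand loading
into the silencing complex. The bundled flank/loop sequences are
synthetic placeholders of realistic length (30/19/30 nt), clearly
labelled as such: the construction algorithm is testable independently
of the literal scaffold sequence, and users supply the authentic
miR-33 arms via `ScaffoldSpec` for production designs.

Intronic insertion defaults to the intron midpoint (maximal distance
from both splice sites); the first and last six intron bases are
protected outright, and non-canonical (non-GT…AG) boundaries warn.

Vector genomes are ordered ITR-to-ITR element lists. Structural rules:
ITRs first and last, exactly one promoter, at most one intron. Size
accounting is exact; the packaging verdict compares total length
(ITRs included — capacity refers to the packaged genome) against
4700 nt for single-stranded and 2400 nt for self-complementary
genomes, both configurable. Elements may be declared by length only
(e.g. proprietary introns); such genomes can be audited and emitted as
GenBank with N-fill but not as FASTA. Oversized genomes get a warning
and an `exceeds` verdict rather than an error so layouts can still be
compared; the intron-swap comparison (1027 vs 384 vs 172 bp → deltas
855/212/0) is the canonical use.

## Sensors and allele quantification

Sensor inserts are `n_sites` tandem sense copies of the allele's
target window separated by a spacer (defaults: one copy, spacer
`TAAT`; copy number for the published sensors is not stated, so the
minimal design is the default). Mutant and wild-type inserts differ at
exactly `n_sites` positions. Normalization is the standard ratio of
ratios, `(RLuc/FLuc)_sample ÷ (RLuc/FLuc)_control`; it is
scale-invariant per well, and the plate helper normalizes to the mean
control ratio. The luciferase readings themselves are experimental
inputs — the package only generates constructs and does arithmetic.

Allele counting uses exact diagnostic k-mers: the SNP base plus
`anchor_len` (default 10) flanking bases on each side, required to be
unique within each allele CDS, searched in both orientations. No
alignment is performed — amplicons fully cover the SNP by design, and
alignment would add failure modes without information. A read counts
only if exactly one allele's k-mer matches and the SNP base quality is
≥ 20 (Phred); everything else, including reads with `N` at the SNP or
any error inside the k-mer, is ambiguous. Counts always sum to the
number of input reads, and fractions are over classified reads, which
makes the estimator unbiased under symmetric substitution error.

## Synthetic fixtures and what the tests show

`synth` generates: random ORFs with human-usage-weighted codons and an
injected missense SNP (resampled deterministically if the configured
change would be synonymous or create a stop); decoy transcriptomes;
GT…AG synthetic introns; a 1530-nt receptor-like CDS (509 codons,
codon 206 fixed to CGC so c.617G>A applies) as a synthetic stand-in
for the real receptor transcript; and amplicon reads drawn from a
two-allele mixture with i.i.d. substitution errors, 50% reverse-
complemented, with base qualities encoding the error rate. All
generators take one seed and are bit-reproducible.

Default simulation conditions: 5,000 reads, 1% substitution error,
and a 65.4% mutant fraction — the allele ratio reported in untreated
patient-derived FOP iPSCs. Under these conditions the counting
pipeline recovers the true fraction within its 99% binomial interval
(checked over 20 seeded replicates per fraction, allowing at most two
misses per fraction, consistent with the 1% per-replicate miss rate of
a 99% interval).

What passing tests do **not** show about real data: the fixtures have
uniform base composition apart from codon usage, no PCR or coverage
bias, no indel errors, no quality-score miscalibration, and the
receptor-like CDS shares only length and composition statistics with
the real transcript — so measured identity percentages and escape
margins on real sequences will differ in detail, though the invariants
(protein preservation, motif hygiene, escape thresholds, exact size
accounting) hold for any valid input.

## Numerical and degenerate-input choices

All computation is integer or exact string arithmetic except the
potency/selectivity scores (plain floating point; no tolerances
needed). Ties anywhere (codon choice, candidate ranking, layout
sorting) are broken deterministically and documented above. Degenerate
inputs: empty transcriptomes scan to zero hits; an empty read stream
yields all-zero counts with fractions flagged undefined (`None`);
missing optimized CDSs make dependent outputs absent rather than zero;
a synonymous "mutation" warns but proceeds. Problem sizes in tests and
the acceptance script (300-nt toy ORFs, one 1530-nt full-length run,
5,000-read simulations, 200-seed property sweeps) were chosen as the
smallest sizes at which every claim is exercised at full fidelity.

## Known limitations

No thermodynamic duplex or RNA secondary-structure modelling (guide
efficacy ranking is heuristic); no Drosha/Dicer processing prediction
for the cassette; no tRNA-adaptation or CpG objectives in the
optimizer; no UMI handling or paired-end merging in counting; ITR
secondary structure and capsid biology are out of scope.
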