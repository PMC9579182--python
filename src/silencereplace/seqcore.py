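"""Sequence records, the genetic code, and FASTA/GenBank/FASTQ plumbing.

Conventions used throughout the package:

* DNA only, over ``{A, C, G, T, N}``; residues are stored uppercase.
  ``N`` is tolerated in sequencing reads but rejected by design inputs
  (the design modules enforce this at their entry points).
* Internal coordinates are 0-based half-open; every user-facing or
  file-format coordinate (GenBank features, HGVS ``c.`` positions,
  target spans) is 1-based inclusive.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TYPE_CHECKING

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._codon_usage import HUMAN_CODON_FRACTIONS

if TYPE_CHECKING:  # pragma: no cover
    from .vector import VectorGenome

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_WITH_N = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file (bad header, illegal residue, truncation)."""


class SequenceError(ValueError):
    """Sequence content violates an operation's preconditions."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class NamedSequence:
    """An identified DNA sequence.

    ``id`` is a short whitespace-free identifier; ``residues`` are
    normalized to uppercase on construction.
    """

    id: str
    residues: str
    description: str = ""
    allow_n: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"sequence id must be non-empty without whitespace: {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        alphabet = DNA_ALPHABET_WITH_N if self.allow_n else DNA_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains characters outside the DNA alphabet: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice1(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.residues)):
            raise SequenceError(
                f"span {start}..{end} outside sequence {self.id!r} of length {len(self)}"
            )
        return self.residues[start - 1 : end]


# ---------------------------------------------------------------------------
# genetic code and codon usage

_STANDARD_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _STANDARD_CODE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class CodonTable:
    """Standard genetic code paired with relative synonymous codon usage.

    ``usage`` maps each codon to its usage frequency scaled within its
    amino-acid family so that the most-used synonymous codon has
    relative usage 1.0. The bundled default is derived from the human
    codon-fraction table.
    """

    code: dict[str, str] = field(default_factory=lambda: dict(_STANDARD_CODE))
    usage: dict[str, float] = field(default_factory=dict)

    @classmethod
    def human(cls) -> "CodonTable":
        by_aa: dict[str, list[str]] = {}
        for codon, aa in _STANDARD_CODE.items():
            by_aa.setdefault(aa, []).append(codon)
        rel: dict[str, float] = {}
        for aa, codons in by_aa.items():
            peak = max(HUMAN_CODON_FRACTIONS[c] for c in codons)
            for c in codons:
                rel[c] = HUMAN_CODON_FRACTIONS[c] / peak
        return cls(usage=rel)

    def amino_acid(self, codon: str) -> str:
        try:
            return self.code[codon]
        except KeyError:
            raise SequenceError(f"not a valid codon: {codon!r}") from None

    def synonyms(self, codon: str) -> list[str]:
        """All codons (incl. the input) encoding the same amino acid."""
        aa = self.amino_acid(codon)
        return sorted(c for c, a in self.code.items() if a == aa)


def translate(cds: str, allow_internal_stop: bool = False) -> str:
    """Translate a CDS with the standard code; trailing stop becomes ``*``.

    Raises on lengths not divisible by 3, on codons containing N, and on
    internal stop codons unless ``allow_internal_stop`` is set.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise SequenceError(f"CDS length {len(cds)} is not divisible by 3")
    protein = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            raise SequenceError(f"ambiguous codon {codon!r} at codon index {i + 1}")
        aa = _STANDARD_CODE.get(codon)
        if aa is None:
            raise SequenceError(f"invalid codon {codon!r} at codon index {i + 1}")
        if aa == "*" and i < n_codons - 1 and not allow_internal_stop:
            raise SequenceError(f"internal stop codon {codon!r} at codon index {i + 1}")
        protein.append(aa)
    return "".join(protein)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, allow_n: bool = False) -> list[NamedSequence]:
    """Strict FASTA reader with line-numbered diagnostics.

    Accepts any wrap width; concatenates wrapped lines; preserves record
    order. Illegal residues or headerless leading sequence raise
    :class:`FormatError` naming the offending line.
    """
    alphabet = DNA_ALPHABET_WITH_N if allow_n else DNA_ALPHABET
    records: list[NamedSequence] = []
    header: tuple[str, str] | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        if not chunks:
            raise FormatError(f"{path}: record {header[0]!r} has no sequence (line {line_no})")
        records.append(
            NamedSequence(header[0], "".join(chunks), description=header[1], allow_n=allow_n)
        )
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                body = line[1:].strip()
                if not body:
                    raise FormatError(f"{path}: empty FASTA header at line {line_no}")
                ident, _, desc = body.partition(" ")
                header = (ident, desc)
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before any header at line {line_no}")
                up = line.upper()
                bad = set(up) - alphabet
                if bad:
                    raise FormatError(
                        f"{path}: illegal residue(s) {sorted(bad)} at line {line_no}"
                    )
                chunks.append(up)
        flush(line_no=-1)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[NamedSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank emission for vector genomes

def write_genbank(genome: "VectorGenome", path: str | Path) -> None:
    """Emit a vector genome as a GenBank flat file.

    One ``misc_feature`` per element with 1-based inclusive coordinates;
    elements declared by length only are filled with N.
    """
    if genome.total_length == 0 or not genome.elements:
        raise SequenceError("cannot write a zero-length genome")
    seq_parts = []
    features = []
    pos = 0  # 0-based running cursor
    for elem in genome.elements:
        seq_parts.append(elem.sequence if elem.sequence is not None else "N" * elem.length)
        loc = FeatureLocation(pos, pos + elem.length)  # half-open internal
        features.append(
            SeqFeature(
                loc,
                type="misc_feature",
                qualifiers={"label": [elem.name], "note": [f"kind:{elem.kind}"]},
            )
        )
        pos += elem.length
    record = SeqRecord(
        Seq("".join(seq_parts)),
        id=genome.name[:16] or "vector",
        name=genome.name[:16] or "vector",
        description=f"{genome.genome_type} AAV vector genome",
        features=features,
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    SeqIO.write(record, str(path), "genbank")


def read_genbank_elements(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read back (name, kind, start, end) feature tuples, 1-based inclusive."""
    record = SeqIO.read(str(path), "genbank")
    out = []
    for feat in record.features:
        if feat.type != "misc_feature":
            continue
        name = feat.qualifiers.get("label", ["?"])[0]
        note = feat.qualifiers.get("note", ["kind:?"])[0]
        kind = note.removeprefix("kind:")
        out.append((name, kind, int(feat.location.start) + 1, int(feat.location.end)))
    return out


# ---------------------------------------------------------------------------
# FASTQ (gzip-transparent)

@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    quals: tuple[int, ...]  # Sanger Phred+33, decoded


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Iterate FASTQ reads (Phred+33), transparently decompressing .gz."""
    with _open_text(path) as fh:
        line_no = 0
        while True:
            head = fh.readline()
            if not head:
                return
            line_no += 1
            if not head.startswith("@"):
                raise FormatError(f"{path}: expected '@' header at line {line_no}")
            seq = fh.readline().strip().upper()
            plus = fh.readline()
            qual = fh.readline().strip()
            line_no += 3
            if not qual or not plus.startswith("+"):
                raise FormatError(f"{path}: truncated FASTQ record at line {line_no}")
            if len(seq) != len(qual):
                raise FormatError(f"{path}: sequence/quality length mismatch at line {line_no}")
            yield FastqRead(head[1:].split()[0], seq, tuple(ord(c) - 33 for c in qual))


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")
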