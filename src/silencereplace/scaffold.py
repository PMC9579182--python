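"""Embed a guide strand in a miR-33-derived pri-amiR cassette.

The cassette layout follows the intronic-amiR cloning scheme:

    PstI site | 5' flank | passenger | loop | guide | 3' flank | BglII site

The passenger strand is the reverse complement of the guide with
declared bulge positions broken (the passenger base is set equal to the
guide base at the aligned position, which always destroys Watson-Crick
pairing in DNA). Cassettes are inserted into an intron between promoter
and transgene, away from both splice sites.

The bundled default flank/loop sequences are synthetic placeholders of
realistic length (the authentic mouse miR-33 scaffold is not bundled);
supply the real scaffold through :class:`ScaffoldSpec` for production
designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .guidewalk import GuideCandidate
from .seqcore import NamedSequence, revcomp

log = logging.getLogger(__name__)


class ScaffoldError(ValueError):
    pass


# Synthetic placeholder scaffold arms (not the authentic miR-33 flanks);
# lengths are realistic for a pri-miRNA cassette: 30/19/30 nt.
_PLACEHOLDER_FIVE_FLANK = "CTGGAGGCTTGCTGAAGGCTGTATGCTGTT"
_PLACEHOLDER_LOOP = "GTTTTGGCCACTGACTGAC"
_PLACEHOLDER_THREE_FLANK = "CAGGACACAAGGCCTGTTACTAGCACTCAC"

PSTI_SITE = "CTGCAG"
BGLII_SITE = "AGATCT"


@dataclass(frozen=True)
class ScaffoldSpec:
    """Scaffold arms, loop, passenger bulge rule, and cloning sites."""

    five_flank: str = _PLACEHOLDER_FIVE_FLANK
    three_flank: str = _PLACEHOLDER_THREE_FLANK
    loop: str = _PLACEHOLDER_LOOP
    passenger_bulges: tuple[int, ...] = (11, 12)  # aligned guide positions left unpaired
    cloning_site_5: str = PSTI_SITE
    cloning_site_3: str = BGLII_SITE

    def __post_init__(self) -> None:
        for name in ("five_flank", "three_flank", "loop"):
            if not getattr(self, name):
                raise ScaffoldError(f"{name} must be non-empty")
        if len(set(self.passenger_bulges)) != len(self.passenger_bulges):
            raise ScaffoldError("duplicate passenger bulge positions")


@dataclass(frozen=True)
class CassetteFeature:
    name: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class AmiRCassette:
    """A pri-amiR hairpin cassette ready for intronic insertion."""

    full_seq: str
    features: tuple[CassetteFeature, ...]
    guide_name: str

    def feature(self, name: str) -> CassetteFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_seq(self, name: str) -> str:
        f = self.feature(name)
        return self.full_seq[f.start - 1 : f.end]


def build_passenger(guide_seq: str, bulges: tuple[int, ...]) -> str:
    """Passenger strand: revcomp(guide) with bulge pairings broken.

    Passenger position ``j`` pairs guide position ``L - j + 1``; a bulge
    at aligned guide position ``p`` substitutes passenger position
    ``L - p + 1`` with the guide base at ``p``, guaranteeing a mismatch.
    """
    L = len(guide_seq)
    for p in bulges:
        if not (1 <= p <= L):
            raise ScaffoldError(f"bulge position {p} outside guide 1..{L}")
    passenger = list(revcomp(guide_seq))
    for p in bulges:
        passenger[L - p] = guide_seq[p - 1]
    return "".join(passenger)


def build_cassette(guide: GuideCandidate, spec: ScaffoldSpec = ScaffoldSpec()) -> AmiRCassette:
    """Assemble the cassette: site5 + 5'flank + passenger + loop + guide + 3'flank + site3.

    Deterministic: the same guide and spec always yield the same sequence.
    """
    passenger = build_passenger(guide.guide_seq, spec.passenger_bulges)
    parts = [
        ("site5", spec.cloning_site_5),
        ("five_flank", spec.five_flank),
        ("passenger", passenger),
        ("loop", spec.loop),
        ("guide", guide.guide_seq),
        ("three_flank", spec.three_flank),
        ("site3", spec.cloning_site_3),
    ]
    features = []
    pos = 1
    for name, seq in parts:
        features.append(CassetteFeature(name, pos, pos + len(seq) - 1))
        pos += len(seq)
    return AmiRCassette(
        full_seq="".join(seq for _, seq in parts),
        features=tuple(features),
        guide_name=guide.name,
    )


def insert_into_intron(
    intron: NamedSequence, cassette: AmiRCassette, position: int | None = None
) -> NamedSequence:
    """Insert the cassette into an intron at a 1-based insertion point.

    ``position`` is the coordinate the cassette's first base will occupy
    (default: the intron's midpoint). The first and last six intron
    bases are protected — they carry the splice donor/acceptor and
    branch-adjacent signals. Canonical GT...AG boundaries are checked
    and warned about, not enforced.
    """
    n = len(intron)
    if position is None:
        position = n // 2 + 1
    if not (1 <= position <= n + 1):
        raise ScaffoldError(f"insertion point {position} outside 1..{n + 1}")
    if position <= 6 or position > n - 5:
        raise ScaffoldError(
            f"insertion at {position} would disrupt splice-site bases (first/last 6 nt protected)"
        )
    if not (intron.residues.startswith("GT") and intron.residues.endswith("AG")):
        log.warning("intron %s lacks canonical GT...AG boundaries", intron.id)
    product = intron.residues[: position - 1] + cassette.full_seq + intron.residues[position - 1 :]
    return NamedSequence(
        f"{intron.id}_{cassette.guide_name}",
        product,
        description=f"{intron.description} + amiR cassette {cassette.guide_name}".strip(),
    )
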