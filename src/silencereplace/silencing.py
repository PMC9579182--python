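"""Dual-luciferase sensor constructs and the screen's normalization arithmetic.

Sensors carry allele target sites in the 3'UTR of Renilla luciferase on
a carrier that also expresses firefly luciferase; silencing of the
sensor is read out as RLuc/FLuc relative to a control well, so lower
relative activity means stronger silencing. This module generates the
three allele-matched sensor inserts (mutant / wild-type / optimized)
for a given guide and performs the ratio-of-ratios normalization on
supplied plate readings; the readings themselves are experimental data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .alleles import AlleleSet
from .guidewalk import GuideCandidate
from .seqcore import NamedSequence

log = logging.getLogger(__name__)


class SensorError(ValueError):
    pass


@dataclass(frozen=True)
class SensorConstruct:
    """One allele sensor: tandem sense target sites for the RLuc 3'UTR."""

    allele_label: str  # "RH" | "WT" | "opt"
    utr_insert: str
    n_sites: int
    spacer: str
    guide_name: str

    @property
    def layout(self) -> str:
        return (
            f"Fluc cassette + RLuc cassette with {self.n_sites} x "
            f"{self.allele_label} target site(s) in the RLuc 3'UTR"
        )

    def as_named(self) -> NamedSequence:
        return NamedSequence(
            f"sensor_{self.allele_label}_{self.guide_name}",
            self.utr_insert,
            description=self.layout,
        )


def build_sensor(
    alleles: AlleleSet,
    guide: GuideCandidate,
    n_sites: int = 1,
    spacer: str = "TAAT",
) -> list[SensorConstruct]:
    """Build the mutant/WT/optimized sensor inserts for one guide.

    Each insert is ``n_sites`` tandem copies of the sense target window
    of the labeled allele, separated by ``spacer``. The mutant and WT
    inserts differ at exactly ``n_sites`` positions (the SNP in each
    copy). When no optimized CDS is present the opt sensor is omitted
    with a warning.
    """
    if n_sites < 1:
        raise SensorError(f"n_sites must be >= 1, got {n_sites}")
    start, end = guide.target_span
    windows = {
        "RH": alleles.mut_cds.slice1(start, end),
        "WT": alleles.wt_cds.slice1(start, end),
    }
    if alleles.opt_cds is not None:
        windows["opt"] = alleles.opt_cds.slice1(start, end)
    else:
        log.warning("no optimized CDS in allele set; opt sensor omitted")
    return [
        SensorConstruct(
            allele_label=label,
            utr_insert=spacer.join([window] * n_sites),
            n_sites=n_sites,
            spacer=spacer,
            guide_name=guide.name,
        )
        for label, window in windows.items()
    ]


@dataclass(frozen=True)
class LuciferaseMeasurement:
    condition: str
    rluc: float
    fluc: float

    def __post_init__(self) -> None:
        if self.fluc <= 0:
            raise SensorError(f"fluc must be positive, got {self.fluc} ({self.condition})")
        if self.rluc < 0:
            raise SensorError(f"rluc must be nonnegative, got {self.rluc} ({self.condition})")


def normalize_luciferase(
    sample: LuciferaseMeasurement, control: LuciferaseMeasurement
) -> float:
    """Relative RLuc/FLuc activity of a sample versus a control well.

    ``(sample.rluc / sample.fluc) / (control.rluc / control.fluc)``;
    1.0 means no silencing, lower means stronger silencing.
    """
    if control.rluc <= 0:
        raise SensorError("control rluc must be positive for normalization")
    return (sample.rluc / sample.fluc) / (control.rluc / control.fluc)


def normalize_plate(measurements: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Normalize a plate table (columns: condition, rluc, fluc).

    Returns the table with a ``relative_activity`` column, each well
    normalized to the mean RLuc/FLuc ratio of the control condition.
    """
    required = {"condition", "rluc", "fluc"}
    if not required.issubset(measurements.columns):
        raise SensorError(f"measurement table needs columns {sorted(required)}")
    if (measurements["fluc"] <= 0).any():
        raise SensorError("all fluc readings must be positive")
    ratios = measurements["rluc"] / measurements["fluc"]
    control_mask = measurements["condition"] == control_condition
    if not control_mask.any():
        raise SensorError(f"control condition {control_condition!r} not found")
    control_ratio = ratios[control_mask].mean()
    if control_ratio <= 0:
        raise SensorError("control RLuc/FLuc ratio must be positive")
    out = measurements.copy()
    out["relative_activity"] = ratios / control_ratio
    return out
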