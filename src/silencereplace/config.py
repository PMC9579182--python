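"""Run configuration: defaults merged with a YAML file and CLI flags.

Every module's tunables live under a namespace (``guidewalk.*``,
``codonopt.*``, ...). Unknown keys are rejected so typos fail loudly;
the effective configuration is echoed into the run manifest.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    pass


DEFAULTS: dict[str, Any] = {
    "guidewalk": {
        "guide_len": 22,
        "snp_offset_min": 2,
        "snp_offset_max": 13,
        "mismatch_position": 14,
        "mismatch_base": "A",
        "weights": {
            "pos1": 0.05,
            "seed": 0.40,
            "central": 0.30,
            "supplementary": 0.10,
            "cap": 1.0,
        },
    },
    "codonopt": {
        "min_relative_codon_freq": 0.10,
        "min_escape_mismatches": 4,
        "gc_window": [50, 0.25, 0.80],
    },
    "scaffold": {
        "passenger_bulges": [11, 12],
        "insertion_position": None,  # None = intron midpoint
    },
    "sensor": {
        "n_sites": 1,
        "spacer": "TAAT",
    },
    "vector": {
        "genome_type": "single_stranded",
        "packaging_limit": None,  # None = default for the genome type
        "intron_length": 172,
        "itr_length": 145,
        "enhancer_length": 380,
        "promoter_length": 280,
        "polya_length": 130,
    },
    "quant": {
        "anchor_len": 10,
        "min_base_qual": 20,
    },
    "synth": {
        "seed": 0,
        "cds_length": 300,
        "snp_codon": 34,
        "n_reads": 5000,
        "mut_fraction": 0.654,
        "error_rate": 0.01,
        "read_length": 100,
    },
}


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict[str, Any]:
    """Defaults, overlaid by a YAML file, overlaid by explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"{path}: config root must be a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg
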