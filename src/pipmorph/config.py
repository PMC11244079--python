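"""Default configuration for the generator and the two-stage analysis.

All tunable parameters live here so a single YAML file can override any of
them.  The shape templates are normalized-EFD feature vectors, harmonic-major
(a1, b1, c1, d1, ..., a6, b6, c6, d6): the wild pip is a rounder oval, the
domestic pip an elongated form whose harmonic-2/3 cosine terms sharpen one
end into a beak.  Both are illustrative defaults, not measurements.
"""

from __future__ import annotations

import copy
from typing import Optional

import yaml

__all__ = ["default_config", "demo_config", "load_config", "merge_config"]


def _template(d1: float, a2: float, a3: float) -> list:
    t = [0.0] * 24
    t[0] = 1.0  # a1: unit semi-axis along x
    t[3] = d1  # d1: semi-axis along y (elongation control)
    t[4] = a2  # a2: egg asymmetry, sharpens the +x end
    t[8] = a3  # a3: beak accent
    return t


DEFAULT_CONFIG: dict = {
    "generator": {
        # Canvas and nominal seed length: 142 px is about 6 mm at 600 dpi,
        # mirroring flatbed-scanner acquisition of real pips.
        "image_size": 512,
        "length_px": 142.0,
        "templates": {
            "wild": _template(d1=0.80, a2=0.03, a3=0.005),
            "domestic": _template(d1=0.55, a2=0.10, a3=0.025),
        },
        # Per-harmonic coefficient standard deviation (applied to all four
        # coefficients of the harmonic); decays with rank as fine detail
        # varies less between seeds than gross shape.
        "coefficient_sd": [0.030, 0.015, 0.010, 0.0075, 0.006, 0.005],
        # Between-cultivar mean spread and within-cultivar spread, as
        # multiples of coefficient_sd.
        "between_cultivar_factor": 1.0,
        "within_cultivar_factor": 0.6,
        "max_retries": 100,
    },
    "analysis": {
        "f_enter": 3.84,
        "f_remove": 2.71,
        "tolerance_min": 0.001,
        "priors": "equal",
        "n_points": 360,
        "min_object_px": 32,
        "stepwise_stage2": True,
        "min_per_cultivar": 3,
        "min_count": 10,
    },
    "reference": {
        # Pools to draw the balanced reference from; stage 1 subsamples an
        # identical number per status class, stage 2 trains on the full
        # domestic pool.
        "n_per_class": 1319,
        "n_wild_pool": 1450,
        "n_cultivars": 330,
        "domestic_per_cultivar": 5,
    },
    "sites": {
        # Unknown-sample sizes follow the archaeological assemblages; the
        # wild mixing fractions are generator conditions chosen to resemble
        # the reported site character, not reproduction targets.
        "well_N": {"n": 1686, "wild_fraction": 0.08},
        "well_KK": {"n": 301, "wild_fraction": 0.26},
        "nora": {"n": 241, "wild_fraction": 0.03},
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def demo_config() -> dict:
    """Small configuration for smoke tests and the packaged demo."""
    cfg = default_config()
    cfg["reference"].update(
        n_per_class=40, n_wild_pool=50, n_cultivars=8, domestic_per_cultivar=6
    )
    cfg["sites"] = {
        "well_N": {"n": 60, "wild_fraction": 0.10},
        "well_KK": {"n": 30, "wild_fraction": 0.30},
    }
    return cfg


def merge_config(base: dict, override: Optional[dict]) -> dict:
    """Recursively merge ``override`` into a deep copy of ``base``."""
    merged = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = merge_config(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(path=None) -> dict:
    """Default configuration, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, override)
    return cfg
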