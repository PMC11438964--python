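"""Run configuration: every design-decision default in one place.

A config is a flat mapping loaded from YAML or JSON.  Unknown keys and
missing required keys raise :class:`ConfigError` naming the offending key.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml

from .types import StimarxError


class ConfigError(StimarxError):
    pass


DEFAULTS: dict[str, Any] = {
    # estimation
    "lam": 0.1,
    "L_grid": [0, 1] + list(range(50, 501, 50)),
    "M_grid": [0, 100, 200, 300],
    "P_grid": list(range(1, 100, 10)) + [100],
    # preprocessing
    "onset_search_halfwidth_ms": 50,
    "onset_threshold_multiple": 5.0,
    # model family
    "tau_cap": 20,
    "ami_bins": 16,
    # causal tests
    "n_boot": 100,
    "alpha": 0.05,
    # network analysis
    "moving_average_width_mm": 20.0,
    "distance_bin_width_mm": 20.0,
    "elimination_threshold": 0.02,
    # synthetic data
    "n_channels": 8,
    "extent_mm": 150.0,
    "family": "sl-arx",
    "gating": "switched",
    "L": 8,
    "M": 5,
    "P": 1,
    "noise_sd": 0.1,
    "stability_margin": 0.95,
    "frequencies": [10, 25, 50, 100, 200, -1],
    "a_safe": 2.0,
    "n_amplitudes": 3,
    "reps": 5,
    "gap_ms": 1500,
    "coupling_band": None,
    "coupling_sources": "all",
    # pipeline
    "stages": ["simulate", "preprocess", "select-order", "compare-families",
               "causal", "distance", "generalize"],
    "container_format": "h5",
}

REQUIRED = ("seed",)


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Merge DEFAULTS <- file <- overrides, validating keys."""
    cfg = dict(DEFAULTS)
    loaded: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = (json.loads(text) if str(path).endswith(".json")
                  else yaml.safe_load(text)) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
    for source in (loaded, overrides or {}):
        for key, val in source.items():
            if key not in DEFAULTS and key not in REQUIRED:
                raise ConfigError(f"unknown config key: {key}")
            cfg[key] = val
    for key in REQUIRED:
        if key not in cfg:
            raise ConfigError(f"missing required config key: {key}")
    return cfg


def amplitude_levels(cfg: dict[str, Any]) -> tuple[float, ...]:
    a = float(cfg["a_safe"])
    levels = (a, a - 0.25, a - 0.5)
    return levels[: int(cfg["n_amplitudes"])]
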