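"""Configuration defaults and YAML loading.

Every tunable of the pipeline lives in one nested mapping so that a site
can override guidance values, processing settings or calibration factors
from a YAML file without touching code.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .analytes import DEFAULT_ANALYTES
from .simulate import K_DEVICE

__all__ = ["default_config", "load_config"]


def default_config() -> dict:
    return {
        "processing": {
            "line_broadening_hz": 0.30,
            "zero_fill_to": None,  # None: use SI from the acquisition parameters
            "baseline": {"lam": None, "p": 0.001, "n_iter": 20},
        },
        "integration": {
            "method": "linefit",
            "n_peaks": 1,
            "windows_ppm": {n: list(a.window_ppm) for n, a in DEFAULT_ANALYTES.items()},
        },
        "quantification": {
            "sample_mass_g": 0.200,
            "extract_volume_mL": 1.5,
            "recalculation_factors": {n: a.recalculation_factor
                                      for n, a in DEFAULT_ANALYTES.items()},
            "eretic_factors": {device: 1.0 / k for device, k in K_DEVICE.items()},
        },
        "limits": {"alpha": 0.01, "k_loq": 3.0},
        "specs": {"recovery_pct": [90.0, 110.0], "cv_pct": 15.0},
        "screening": {
            "omc_arabica_max_mg_kg": 50.0,
            "caffeine_decaf_max_mg_kg": 1000.0,
            "kahweol_robusta_max_mg_kg": None,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, deep-merged with an optional YAML override file."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    return cfg
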