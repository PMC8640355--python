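"""YAML configuration loading.

A config file holds up to four sections, each optional and each merged over
the dataclass defaults documented in the respective module::

    simulate:            # ramanembryo.synthetic.SimConfig fields
      n_blastula: 80
      group_effect_scale: 1.0   # convenience: scales the default effects
    preprocess:          # ramanembryo.preprocessing.PreprocessParams fields
      lam: 1.0e5
      p: 0.01
    mlp:                 # ramanembryo.classifier.MLPConfig fields
      max_epochs: 300
      n_per_group: 30    # training samples drawn per group
    screening:
      threshold: 3.0
      standardize: true
      merge_gap: 4.0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .classifier import MLPConfig
from .preprocessing import PreprocessParams
from .synthetic import BaselineParams, GroupEffect, PeakSpec, SimConfig, default_group_effects


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return data


def sim_config_from_dict(section: dict, seed: int | None = None) -> SimConfig:
    section = dict(section or {})
    if "group_effect_scale" in section:
        section["group_effects"] = default_group_effects(float(section.pop("group_effect_scale")))
    if "group_effects" in section and section["group_effects"] is not None:
        section["group_effects"] = tuple(
            e if isinstance(e, GroupEffect) else GroupEffect(**e) for e in section["group_effects"]
        )
    if "peak_bank" in section and section["peak_bank"] is not None:
        section["peak_bank"] = tuple(
            p if isinstance(p, PeakSpec) else PeakSpec(**p) for p in section["peak_bank"]
        )
    if "baseline" in section and not isinstance(section["baseline"], BaselineParams):
        b = dict(section["baseline"])
        if "poly" in b:
            b["poly"] = tuple(b["poly"])
        section["baseline"] = BaselineParams(**b)
    if seed is not None:
        section["seed"] = seed
    return SimConfig(**section)


def preprocess_params_from_dict(section: dict) -> PreprocessParams:
    return PreprocessParams(**(section or {}))


def mlp_config_from_dict(section: dict, seed: int | None = None) -> tuple[MLPConfig, int]:
    """Returns (MLPConfig, n_per_group)."""
    section = dict(section or {})
    n_per_group = int(section.pop("n_per_group", 30))
    if "hidden_units" in section:
        section["hidden_units"] = tuple(section["hidden_units"])
    if seed is not None:
        section["seed"] = seed
    return MLPConfig(**section), n_per_group
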