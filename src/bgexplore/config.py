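"""Configuration handling.

The packaged ``defaults.yaml`` holds every constant of the model - neuron
parameters per population, synapse constants, projection table, plasticity
and task parameters - and named presets (``desk`` for quick reduced-size
runs, ``full`` for the full-scale network).  User YAML files are merged
over the defaults.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "merge"]


def _defaults() -> dict:
    text = resources.files("bgexplore").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def merge(base: dict, override: dict) -> dict:
    """Recursive dict merge; ``override`` wins, nested dicts are merged."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config(preset: str | None = None, overrides: dict | None = None) -> dict:
    """The default configuration, optionally with a preset and overrides applied."""
    cfg = _defaults()
    presets = cfg.pop("presets", {})
    if preset is not None:
        if preset not in presets:
            raise KeyError(f"unknown preset {preset!r}; available: {sorted(presets)}")
        cfg = merge(cfg, presets[preset] or {})
    if overrides:
        cfg = merge(cfg, overrides)
    return cfg


def load_config(path: str | Path, preset: str | None = None) -> dict:
    """Defaults merged with a user YAML file (applied after the preset)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return default_config(preset=preset, overrides=user)
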