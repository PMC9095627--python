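"""Shared run configuration.

One YAML schema drives every stage: registry block, kinetic model block,
uptake/spectral blocks for the synthetic generator, and analysis settings.
The packaged ``data/default_config.yaml`` holds the default calibration;
user configs may override any subset of keys.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import json
from typing import Any

import yaml

__all__ = ["load_default_config", "load_config", "save_config", "config_hash",
           "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run config is structurally invalid; message names the key."""


_REQUIRED_TOP = ("registry", "model", "uptake", "spectral", "analysis")


def load_default_config() -> dict[str, Any]:
    """The packaged default calibration, as a plain dict."""
    text = (importlib.resources.files("persist") / "data" / "default_config.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | None = None, require_seed: bool = False) -> dict[str, Any]:
    """Load a run config, layering ``path`` over the packaged defaults."""
    cfg = load_default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
        cfg = _merge(cfg, user)
    for key in _REQUIRED_TOP:
        if key not in cfg:
            raise ConfigError(f"missing required config block: {key}")
    if require_seed and "seed" not in cfg:
        raise ConfigError("missing required key: seed (stochastic stages need a master seed)")
    return cfg


def save_config(cfg: dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a config, for provenance stamps."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
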