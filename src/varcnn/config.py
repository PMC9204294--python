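"""Run configuration: shipped defaults deep-merged with a user YAML file."""

from __future__ import annotations

import copy
from importlib import resources

import yaml


def default_config() -> dict:
    with resources.files("varcnn").joinpath("data/default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(out[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Load ``path`` (YAML) on top of the shipped defaults.

    Unknown keys raise, so typos fail loudly instead of silently running the
    defaults.
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(cfg, user)
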