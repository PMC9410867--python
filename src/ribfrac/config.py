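"""Flat YAML config handling shared by the CLI subcommands.

A config file holds flat ``key: value`` pairs drawn from the dataclass
fields of the stage configs; unknown keys are rejected with the list of
accepted names. Explicit command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = ["load_config", "build_dataclass"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config file must hold a flat mapping, got {type(data).__name__}")
    return data


def build_dataclass(cls, file_values: dict, overrides: dict):
    """Instantiate a config dataclass from file values + explicit overrides.

    ``overrides`` entries that are None are treated as "not given". Keys in
    ``file_values`` that match no field of ``cls`` are rejected.
    """
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(file_values) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; accepted: {sorted(fields)}"
        )
    merged = dict(file_values)
    for k, v in overrides.items():
        if v is not None:
            if k not in fields:
                raise ValueError(f"unknown option {k!r} for {cls.__name__}")
            merged[k] = v
    # coerce list-valued YAML entries to tuples where the field expects one
    for k, v in list(merged.items()):
        if isinstance(v, list):
            merged[k] = tuple(v)
    return cls(**merged)
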