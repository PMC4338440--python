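"""Parameter-file loading for the binding model.

Config files are YAML or JSON mappings whose keys mirror
:class:`ftds.model.ModelParams` field names exactly; the affinity preset is
selected by name (``initial_hierarchy``, ``revised_hierarchy``, ``custom``).
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path

import yaml

from ftds.model import ModelParams

__all__ = ["load_params", "dump_params"]

_FIELD_NAMES = {f.name for f in fields(ModelParams)}


def load_params(path) -> ModelParams:
    """Read model parameters from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a parameter mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParams(**data)


def dump_params(params: ModelParams, path) -> None:
    """Write model parameters as YAML (or JSON for a .json suffix)."""
    path = Path(path)
    data = {f.name: getattr(params, f.name) for f in fields(ModelParams)}
    data["affinity_preset"] = params.affinity_preset.value
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
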