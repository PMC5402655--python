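"""Shared scoring configuration, loadable from a JSON or YAML file.

A configuration file is a flat mapping with any of the keys::

    inventory: [list of construct identifiers]      # richness denominator
    consistency_formula: distinct-ratio | duplicate-fraction
    branch_weights: {syntactic: w, semantic: w, pragmatic: w, social: w}
    sub_weights: {branch: {subscore: w, ...}, ...}

Anything omitted falls back to the documented defaults (the full 20-item
construct inventory, the distinct-ratio consistency formula and equal
weights with authority excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .aggregation import EQUAL_WEIGHTS, WeightConfig
from .errors import ConfigurationError
from .inventory import DEFAULT_INVENTORY, FeatureInventory


@dataclass(frozen=True)
class ScoringConfig:
    inventory: FeatureInventory = DEFAULT_INVENTORY
    weights: WeightConfig = EQUAL_WEIGHTS
    consistency_formula: str = "distinct-ratio"

    @classmethod
    def from_mapping(cls, data: dict) -> "ScoringConfig":
        if not isinstance(data, dict):
            raise ConfigurationError("configuration must be a mapping")
        inventory = DEFAULT_INVENTORY
        if "inventory" in data:
            inventory = FeatureInventory(tuple(data["inventory"]))
        weights = EQUAL_WEIGHTS
        if "branch_weights" in data or "sub_weights" in data:
            kwargs = {}
            if "branch_weights" in data:
                kwargs["branch_weights"] = dict(data["branch_weights"])
            if "sub_weights" in data:
                kwargs["sub_weights"] = {
                    b: dict(g) for b, g in data["sub_weights"].items()
                }
            weights = WeightConfig(**kwargs)
        return cls(
            inventory=inventory,
            weights=weights,
            consistency_formula=data.get("consistency_formula", "distinct-ratio"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringConfig":
        path = Path(path)
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_mapping(data or {})


DEFAULT_CONFIG = ScoringConfig()
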