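"""YAML/JSON configuration loading for models, dosages and grids.

A config file contains any of the blocks ``model:``, ``dosage:``,
``gal3:`` and ``grid:`` whose keys are the corresponding dataclass fields,
e.g. ::

    model:
      lambda_g: 0.1
      mu: 30.0
    dosage:
      q_g: 0.35
      q_r: 2
    grid:
      n_nodes: 401
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from galshuttle.model import (
    DosageConfig,
    Gal3Config,
    ModelParameters,
    SpatialGrid,
    reference_parameters,
)

__all__ = ["load_config", "model_from_config", "dosage_from_config",
           "gal3_from_config", "grid_from_config"]


def load_config(path) -> dict:
    """Read a YAML (or JSON) config file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def model_from_config(cfg: dict) -> ModelParameters:
    """Model parameters from the ``model:`` block.

    ``model: reference`` (or ``base: reference`` inside the block) starts
    from the calibrated reference set; explicit fields override it.
    """
    block = cfg.get("model", {})
    if block == "reference":
        return reference_parameters()
    if isinstance(block, dict) and block.get("base") == "reference":
        base = reference_parameters()
        fields = {k: v for k, v in block.items() if k != "base"}
        from dataclasses import replace
        return replace(base, **fields)
    return ModelParameters(**block)


def dosage_from_config(cfg: dict) -> DosageConfig:
    return DosageConfig(**cfg.get("dosage", {}))


def gal3_from_config(cfg: dict):
    if "gal3" not in cfg or cfg["gal3"] is None:
        return None
    return Gal3Config(**cfg["gal3"])


def grid_from_config(cfg: dict) -> SpatialGrid:
    block = cfg.get("grid", {})
    return SpatialGrid.uniform(int(block.get("n_nodes", 401)))
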