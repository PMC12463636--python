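"""Default configuration loading.

All tunable geometry (panel, population model, gates, risk trees) ships as
YAML package data so that sites can override any of it without touching
code. Loaders return plain dicts; the consuming modules validate.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml


def _load_packaged_yaml(name: str) -> dict[str, Any]:
    with resources.files("mrdlite.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_panel_config(path: str | Path | None = None) -> dict[str, Any]:
    """Panel definition: required channels per tube plus the alias map."""
    if path is None:
        return _load_packaged_yaml("panel.yaml")["panel"]
    with open(path) as fh:
        return yaml.safe_load(fh)["panel"]


def load_population_config(path: str | Path | None = None) -> dict[str, Any]:
    """Synthetic-marrow geometry, composition and preparation factors."""
    if path is None:
        return _load_packaged_yaml("populations.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_gate_config(path: str | Path | None = None) -> dict[str, Any]:
    """Gate geometry, marker thresholds and cluster/LOD settings."""
    if path is None:
        return _load_packaged_yaml("gates.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_risk_tree_config(path: str | Path | None = None) -> dict[str, Any]:
    """Risk-stratification decision trees (ORIGINAL and UPDATED workflows)."""
    if path is None:
        return _load_packaged_yaml("risk_tree.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)
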