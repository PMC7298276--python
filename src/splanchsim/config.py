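"""Configuration loading: circuit parameters, model state and scenarios
from JSON or TOML files.

Keys follow the dataclass field names verbatim, e.g.::

    {"source_voltage": 12.0, "r_ca": 3300, "r_pda": 3300,
     "r_pancreas_liver": 12000, "pot_min": 0, "pot_max": 50000}
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import fields
from pathlib import Path

from .model import ModelState, SplanchnicParameters
from .scenario import Scenario

__all__ = ["load_document", "load_parameters", "load_state", "load_scenario"]


def load_document(path: str | Path) -> dict:
    """Parse a JSON or TOML document by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    raise ValueError(f"unsupported config format {path.suffix!r} "
                     "(expected .json or .toml)")


def _pick(d: dict, cls) -> dict:
    names = {f.name for f in fields(cls)}
    return {k: v for k, v in d.items() if k in names}


def load_parameters(path: str | Path) -> SplanchnicParameters:
    d = load_document(path)
    d = d.get("parameters", d)
    return SplanchnicParameters(**_pick(d, SplanchnicParameters))


def load_state(path: str | Path) -> ModelState:
    d = load_document(path)
    d = d.get("state", d)
    return ModelState(**_pick(d, ModelState))


def load_scenario(path: str | Path) -> Scenario:
    return Scenario.from_dict(load_document(path))
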