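"""Provenance-tagged configuration handling.

Every numeric parameter in the packaged default configs is stored as a
mapping ``{value: <number>, provenance: <tag>}`` where the tag is one of

* ``main-text``  -- the number is part of the modelled experimental setup
  and must not be changed casually;
* ``calibrated`` -- the number is a package default chosen to reproduce
  the qualitative regime map (no published value is available);
* ``user``       -- the number was overridden at run time.

``resolve`` strips the tags into a plain nested dict of values;
``audit_provenance`` walks a config and raises if any numeric leaf lacks
a tag, so runs fail loudly on hand-edited configs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from typing import Any

import yaml

VALID_PROVENANCE = {"main-text", "calibrated", "user"}


class ConfigError(ValueError):
    """Raised for malformed or unprovenanced configuration."""


def _is_tagged(node: Any) -> bool:
    return isinstance(node, dict) and set(node) >= {"value", "provenance"}


def load_packaged(name: str) -> dict:
    """Load a packaged default config (e.g. ``rate_defaults``)."""
    text = resources.files("vipcircuit.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def load_file(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def resolve(node: Any) -> Any:
    """Strip provenance tags, returning plain values."""
    if _is_tagged(node):
        return node["value"]
    if isinstance(node, dict):
        return {k: resolve(v) for k, v in node.items()}
    if isinstance(node, list):
        return [resolve(v) for v in node]
    return node


def audit_provenance(node: Any, path: str = "") -> None:
    """Raise ConfigError if any numeric leaf lacks a provenance tag."""
    if _is_tagged(node):
        if node["provenance"] not in VALID_PROVENANCE:
            raise ConfigError(f"{path}: unknown provenance {node['provenance']!r}")
        return
    if isinstance(node, dict):
        for k, v in node.items():
            audit_provenance(v, f"{path}.{k}" if path else str(k))
        return
    if isinstance(node, list):
        for i, v in enumerate(node):
            audit_provenance(v, f"{path}[{i}]")
        return
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        raise ConfigError(f"{path}: numeric value {node!r} lacks a provenance tag")


def override(config: dict, dotted_key: str, value: Any) -> dict:
    """Return a copy of ``config`` with one tagged leaf replaced (tag 'user')."""
    out = copy.deepcopy(config)
    node = out
    keys = dotted_key.split(".")
    for k in keys[:-1]:
        node = node[int(k)] if isinstance(node, list) else node[k]
    leaf = keys[-1]
    tgt = node[int(leaf)] if isinstance(node, list) else node[leaf]
    if _is_tagged(tgt):
        new = {"value": value, "provenance": "user"}
    else:
        new = value
    if isinstance(node, list):
        node[int(leaf)] = new
    else:
        node[leaf] = new
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of a config for run logging."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
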