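"""Access to the packaged default parameter table.

All defaults live in ``data/parameters.yaml``; each entry carries a
``source: paper|default`` provenance tag.  :func:`load_parameters` returns the
raw tagged tree, :func:`parameter_values` strips the tags for consumption by
the simulation layer.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml


@lru_cache(maxsize=1)
def load_parameters() -> dict[str, Any]:
    """Return the full parameter table including provenance tags."""
    ref = resources.files("mimosa.data").joinpath("parameters.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _strip(node: Any) -> Any:
    if isinstance(node, dict):
        if "value" in node and "source" in node:
            return node["value"]
        return {k: _strip(v) for k, v in node.items()}
    return node


@lru_cache(maxsize=1)
def parameter_values() -> dict[str, Any]:
    """Return the parameter table with provenance tags stripped."""
    return _strip(load_parameters())


def get(*keys: str) -> Any:
    """Walk the stripped table, e.g. ``get('cell', 'sd_fraction')``."""
    node: Any = parameter_values()
    for key in keys:
        node = node[key]
    return node
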