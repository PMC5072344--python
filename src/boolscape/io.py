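"""File I/O helpers: network files, YAML analysis configs, TSV exports."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .landscape import MARKER_ROLES, MarkerConfig
from .network import (BooleanNetwork, Mutation, MutationProfile, parse_bnet,
                      serialize_bnet)


def load_bnet(path) -> BooleanNetwork:
    return parse_bnet(Path(path).read_text())


def save_bnet(network: BooleanNetwork, path) -> None:
    Path(path).write_text(serialize_bnet(network))


def load_analysis_config(path) -> tuple[MarkerConfig, MutationProfile]:
    """Read the YAML analysis config.

    Schema::

        markers:
          cyclinD: CyclinD
          ...            # all eight roles
        inputs:
          on:  [EGF, ECM, Wnt]
          off: [DNAdam]
        mutations:
          - {node: APC,  value: 0, label: APC}
          - {node: KRAS, value: 1, label: KRAS}
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "markers" not in doc:
        raise ValueError("config must be a mapping with a 'markers' section")
    markers_doc = doc["markers"]
    missing = [r for r in MARKER_ROLES if r not in markers_doc]
    if missing:
        raise ValueError(f"config missing marker roles: {missing}")
    inputs = doc.get("inputs", {}) or {}
    # YAML 1.1 parses bare on/off as booleans; accept either spelling
    on_list = inputs.get("on", inputs.get(True, [])) or []
    off_list = inputs.get("off", inputs.get(False, [])) or []
    markers = MarkerConfig(
        **{r: str(markers_doc[r]) for r in MARKER_ROLES},
        inputs_on=tuple(on_list),
        inputs_off=tuple(off_list),
    )
    profile = MutationProfile([
        Mutation(str(m["node"]), int(m["value"]), str(m.get("label", m["node"])))
        for m in (doc.get("mutations", []) or [])
    ])
    return markers, profile


def save_analysis_config(markers: MarkerConfig, profile: MutationProfile,
                         path) -> None:
    doc = {
        "markers": markers.marker_nodes(),
        "inputs": {"on": list(markers.inputs_on),
                   "off": list(markers.inputs_off)},
        "mutations": [{"node": m.node, "value": m.value, "label": m.label}
                      for m in profile],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
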