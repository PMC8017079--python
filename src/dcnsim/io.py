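"""Config serialization: parameter sets, protocols and variant specs as JSON.

Round trips are lossless; schema violations are reported with field paths.
A missing optional calibration constant (e.g. C_KCa) falls back to its
package default with a logged warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Union

from .params import GatingSpec, ModelParameters
from .stimulus import PulseSpec, StimulusProtocol
from .variants import VariantSpec

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = ["save_config", "load_config", "to_dict", "from_dict"]

_TYPES = {
    "model_parameters": ModelParameters,
    "stimulus_protocol": StimulusProtocol,
    "variant_spec": VariantSpec,
}

#: calibration constants that may be absent from a config file
_OPTIONAL_DEFAULTS = {"C_KCa", "Ca_base", "Ca_out"}


def to_dict(obj: Union[ModelParameters, StimulusProtocol, VariantSpec]) -> dict:
    if isinstance(obj, ModelParameters):
        d = dataclasses.asdict(obj)
        d["gating"] = {k: dataclasses.asdict(v) for k, v in obj.gating.items()}
        kind = "model_parameters"
    elif isinstance(obj, StimulusProtocol):
        d = {"I_DC": obj.I_DC,
             "pulses": [dataclasses.asdict(p) for p in obj.pulses]}
        kind = "stimulus_protocol"
    elif isinstance(obj, VariantSpec):
        d = {"edits": [list(e) for e in obj.edits],
             "h_CaT_frozen": obj.h_CaT_frozen, "ca_frozen": obj.ca_frozen}
        kind = "variant_spec"
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    return {"schema": SCHEMA_VERSION, "kind": kind, "data": d}


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{path}: unknown fields {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def from_dict(doc: dict) -> Union[ModelParameters, StimulusProtocol, VariantSpec]:
    if doc.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema {doc.get('schema')!r}")
    kind = doc.get("kind")
    if kind not in _TYPES:
        raise ValueError(f"unknown config kind {kind!r}")
    data = dict(doc["data"])
    if kind == "model_parameters":
        defaults = ModelParameters()
        for name in _OPTIONAL_DEFAULTS - set(data):
            data[name] = getattr(defaults, name)
            log.warning("config missing %s; using default %g", name, data[name])
        gating = data.get("gating", {})
        data["gating"] = {k: _build(GatingSpec, v, f"gating.{k}")
                          for k, v in gating.items()}
        return _build(ModelParameters, data, "model_parameters")
    if kind == "stimulus_protocol":
        pulses = tuple(_build(PulseSpec, p, f"pulses[{i}]")
                       for i, p in enumerate(data.get("pulses", [])))
        return _build(StimulusProtocol,
                      {"I_DC": data.get("I_DC", 0.0), "pulses": pulses},
                      "stimulus_protocol")
    data["edits"] = tuple((str(p), v) for p, v in data.get("edits", []))
    return _build(VariantSpec, data, "variant_spec")


def save_config(obj, path) -> None:
    Path(path).write_text(json.dumps(to_dict(obj), indent=2, sort_keys=True)
                          + "\n")


def load_config(path):
    return from_dict(json.loads(Path(path).read_text()))
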