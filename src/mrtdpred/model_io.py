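"""Flat JSON import/export for fitted dose models."""

from __future__ import annotations

import json
from pathlib import Path

from .linear import DescriptorLinearRegression
from .network import NetworkSpec, TanhNetworkRegressor


def model_to_dict(model) -> dict:
    if isinstance(model, DescriptorLinearRegression):
        return model.to_dict()
    if isinstance(model, TanhNetworkRegressor):
        return model.network_.to_dict()
    if isinstance(model, NetworkSpec):
        return model.to_dict()
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def model_from_dict(doc: dict):
    kind = doc.get("kind")
    if kind == "linear":
        return DescriptorLinearRegression.from_dict(doc)
    if kind == "network":
        return TanhNetworkRegressor.from_spec(NetworkSpec.from_dict(doc))
    raise ValueError(f"unknown model kind {kind!r}")


def save_model(model, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def load_model(path):
    return model_from_dict(json.loads(Path(path).read_text()))
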