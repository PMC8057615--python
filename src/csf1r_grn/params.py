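"""Kinetic parameter handling.

Parameters are a flat mapping from symbol to value. Symbols follow the
edge numbering of the packaged regulation table and the component names:

========================  =====================================================
``kd_<COMP>``             mRNA degradation rate constant, 1/h
``b_<COMP>``              basal (regulator-independent) transcription, conc/h
``w<id>``                 maximal transcription-rate contribution of
                          transcriptional activation edge ``<id>``, conc/h
``K<id>``, ``n<id>``      half-saturation activity and Hill exponent of
                          edge ``<id>`` (activation or inhibition)
``wa<id>``                maximal protein-activation rate contribution of
                          post-translational edge ``<id>``, 1/h
``Ka<id>``, ``na<id>``    half-saturation activity and Hill exponent of
                          post-translational edge ``<id>``
``kdp_<COMP>``            protein degradation rate constant, 1/h
``ki_<COMP>``             protein inactivation rate constant, 1/h
``ba_<COMP>``             basal protein-activation rate, 1/h
``protein_mrna_ratio``    steady-state protein/mRNA abundance ratio (3000)
========================  =====================================================

Edges whose source is the external LPS input act linearly in the LPS
level (``w<id>``/``wa<id>`` only, no half-saturation), except the
inhibitory LPS edge which uses an even-exponent saturating factor so the
model remains smooth when continuation explores negative LPS.

mRNA protein synthesis rates are not free symbols: each active-form
component synthesises protein at ``protein_mrna_ratio * kdp`` per unit
mRNA, which pins the steady-state total-protein/mRNA ratio exactly.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

__all__ = ["ParameterSet", "load_params", "default_params", "write_params", "half_life"]


class ParameterSet(Mapping):
    """Immutable-by-convention mapping of kinetic symbols to values."""

    def __init__(self, values: Mapping[str, float], meta: dict | None = None):
        bad = [k for k, v in values.items() if not np.isfinite(v) or v < 0]
        if bad:
            raise ValueError(f"non-finite or negative parameter(s): {bad}")
        self._values = dict(values)
        self.meta = dict(meta or {})

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def replace(self, **updates: float) -> "ParameterSet":
        """New ParameterSet with some symbols replaced."""
        unknown = set(updates) - set(self._values)
        if unknown:
            raise KeyError(f"unknown parameter symbol(s): {sorted(unknown)}")
        vals = dict(self._values)
        vals.update(updates)
        return ParameterSet(vals, self.meta)

    def scaled(self, factors: Mapping[str, float]) -> "ParameterSet":
        """New ParameterSet with per-symbol multiplicative factors applied."""
        vals = dict(self._values)
        for k, f in factors.items():
            vals[k] = vals[k] * f
        return ParameterSet(vals, self.meta)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)


def load_params(path: str | Path) -> ParameterSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    meta = doc.pop("_meta", {})
    return ParameterSet({k: float(v) for k, v in doc.items()}, meta)


def default_params() -> ParameterSet:
    """The packaged calibrated parameter set."""
    text = resources.files("csf1r_grn.data").joinpath("parameters.yaml").read_text()
    doc = yaml.safe_load(text)
    meta = doc.pop("_meta", {})
    return ParameterSet({k: float(v) for k, v in doc.items()}, meta)


def write_params(params: ParameterSet, path: str | Path) -> None:
    doc: dict = {}
    if params.meta:
        doc["_meta"] = params.meta
    doc.update({k: float(v) for k, v in params.to_dict().items()})
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def half_life(params: ParameterSet, component: str) -> float:
    """mRNA half-life of ``component`` in hours, ln(2)/kd."""
    try:
        kd = params[f"kd_{component}"]
    except KeyError:
        raise KeyError(f"no mRNA degradation constant for {component!r}") from None
    return math.log(2.0) / kd
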