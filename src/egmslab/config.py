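"""YAML/JSON configuration loading for slab, membrane and wave parameters.

Schema (all keys optional, defaults are the reference parameter set)::

    conductivities: {g_i_l, g_i_t, g_e_l, g_e_t, g_B, g_T}   # S/m
    slab:           {L_mm, psi_deg}
    membrane:       {phi_rest_mV, phi_max_mV}
    wave:           {v_parallel_m_per_s}
    bipolar_sign:   +1 | -1        # distal-minus-proximal by default
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError
from .tissue_model import (
    DEFAULT_CONDUCTIVITIES,
    DEFAULT_V_PARALLEL,
    ConductivitySet,
    MembraneStep,
    SlabModel,
)

__all__ = ["ModelConfig", "load_config"]


@dataclass(frozen=True)
class ModelConfig:
    slab: SlabModel
    membrane: MembraneStep
    v_parallel: float
    bipolar_sign: int

    @property
    def conductivities(self) -> ConductivitySet:
        return self.slab.conductivities


def _build(raw: dict) -> ModelConfig:
    cond_kw = raw.get("conductivities", {})
    if cond_kw:
        cs = ConductivitySet(**cond_kw)
    else:
        cs = DEFAULT_CONDUCTIVITIES
    slab_kw = raw.get("slab", {})
    slab = SlabModel(cs, L=slab_kw.get("L_mm", 5.0), psi=slab_kw.get("psi_deg", 0.0))
    mem_kw = raw.get("membrane", {})
    mem = MembraneStep(
        phi_max=mem_kw.get("phi_max_mV", 10.0),
        phi_rest=mem_kw.get("phi_rest_mV", -86.0),
    )
    v = raw.get("wave", {}).get("v_parallel_m_per_s", DEFAULT_V_PARALLEL)
    sign = int(raw.get("bipolar_sign", 1))
    if sign not in (1, -1):
        raise InvalidParameterError("bipolar_sign must be +1 or -1")
    return ModelConfig(slab=slab, membrane=mem, v_parallel=v, bipolar_sign=sign)


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a model configuration; no path returns the defaults."""
    if path is None:
        return _build({})
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _build(raw or {})
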