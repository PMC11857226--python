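"""YAML (de)serialisation of model parameters and reactor geometry.

A parameter file looks like::

    arrhenius:
      k0: {A: 1.9555e15, Ea_kJ_per_mol: 89.60}
      k1: {A: 1.4989e13, Ea_kJ_per_mol: 71.77}
      k2: {A: 8.0898e17, Ea_kJ_per_mol: 104.07}
      k3: {A: 5.3287e14, Ea_kJ_per_mol: 78.49}
    K: 1.0e4
    C_cat0: 2.0e-5
    active_species_mode: complex-active

and a reactor geometry file like::

    sections:
      - {inner_diameter_mm: 1.0, length_m: 2.0, count: 4}
      - {inner_diameter_mm: 2.0, length_m: 2.0, count: 2}
    accessory_volume_mL: 0.13
    total_flow_rate_mL_min: 20.4

Omitted parameter keys fall back to the package defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .kinetic_core import (
    DEFAULT_ARRHENIUS,
    DEFAULT_C_CAT0,
    DEFAULT_K,
    ArrheniusLaw,
    CatalystSpec,
    ModelParams,
)
from .reactor import FlowConfig, TubeSection


def params_to_dict(params: ModelParams) -> dict:
    return {
        "arrhenius": {
            name: {"A": law.A, "Ea_kJ_per_mol": law.Ea}
            for name, law in sorted(params.arrhenius_laws.items())
        },
        "K": params.K,
        "C_cat0": params.catalyst.C_cat0,
        "active_species_mode": params.catalyst.active_species_mode,
    }


def params_from_dict(d: dict) -> ModelParams:
    laws = dict(DEFAULT_ARRHENIUS)
    for name, entry in (d.get("arrhenius") or {}).items():
        laws[name] = ArrheniusLaw(A=float(entry["A"]),
                                  Ea=float(entry["Ea_kJ_per_mol"]))
    return ModelParams(
        arrhenius_laws=laws,
        K=float(d.get("K", DEFAULT_K)),
        catalyst=CatalystSpec(
            C_cat0=float(d.get("C_cat0", DEFAULT_C_CAT0)),
            active_species_mode=d.get("active_species_mode", "complex-active"),
        ),
    )


def load_params(path: str | Path) -> ModelParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return params_from_dict(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def load_flow_config(path: str | Path) -> FlowConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sections = [
        TubeSection(
            inner_diameter_mm=float(s["inner_diameter_mm"]),
            length_m=float(s["length_m"]),
            count=int(s.get("count", 1)),
        )
        for s in data.get("sections", [])
    ]
    return FlowConfig(
        sections=tuple(sections),
        total_flow_rate_mL_min=float(data["total_flow_rate_mL_min"]),
        accessory_volume_mL=float(data.get("accessory_volume_mL", 0.0)),
    )
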