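"""Run configuration: functional units, breed and energy factors, overrides.

A YAML file with flat sections, e.g.::

    functional_units:
      - {name: utilised agricultural area, quantity: 70632, units: ha}
    live_weight_c_fraction: 0.18        # breed-specific, within [0.15, 0.20]
    electricity_kg_c_per_kwh: 0.09      # national inventory value
    coefficients:                       # registry overrides / additions
      - {material: wood, basis: mass_fraction, value: 0.49, source: "lab assay"}
    report_decimals: {total: 1, per_fu: 2}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conversion import CoefficientRegistry
from .model import FunctionalUnit


@dataclass
class RunConfig:
    functional_units: list[FunctionalUnit] = field(default_factory=list)
    live_weight_c_fraction: float | None = None
    electricity_kg_c_per_kwh: float | None = None
    registry: CoefficientRegistry = field(default_factory=CoefficientRegistry)
    report_decimals: dict[str, int] = field(default_factory=lambda: {"total": 1, "per_fu": 2})


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = RunConfig()
    for fu in raw.get("functional_units", []):
        cfg.functional_units.append(
            FunctionalUnit(fu["name"], float(fu["quantity"]), fu["units"])
        )
    if "live_weight_c_fraction" in raw:
        cfg.live_weight_c_fraction = float(raw["live_weight_c_fraction"])
        cfg.registry.set_live_weight_fraction(cfg.live_weight_c_fraction, "configuration file")
    if "electricity_kg_c_per_kwh" in raw:
        cfg.electricity_kg_c_per_kwh = float(raw["electricity_kg_c_per_kwh"])
        cfg.registry.set_electricity_factor(cfg.electricity_kg_c_per_kwh, "configuration file")
    for entry in raw.get("coefficients", []):
        cfg.registry.set(
            entry["material"],
            entry["basis"],
            float(entry["value"]),
            entry.get("source", "configuration file"),
        )
    if "report_decimals" in raw:
        cfg.report_decimals.update(
            {k: int(v) for k, v in raw["report_decimals"].items()}
        )
    return cfg
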