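"""Packaged validation datasets.

``coalvi()`` loads the published whole-consortium beef-farm validation case:
14 distinct carbon fluxes (the source table prints 17 rows because each of
the three internal transfers appears once in the sending and once in the
receiving sector block) among the animal, plant, soil, air and external
sites, in thousands of tonnes of carbon per year, together with the two
functional units (utilised agricultural area and slaughtered live weight)
implied by the table's per-unit columns.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import yaml

from .io import read_ledger
from .model import FunctionalUnit, SystemLedger

_DATA = resources.files(__package__) / "data"


def coalvi_csv_text() -> str:
    """Raw text of the packaged consortium ledger CSV."""
    return (_DATA / "coalvi_table1.csv").read_text(encoding="utf-8")


def coalvi_checksum() -> str:
    """SHA-256 of the packaged fixture, for byte-stability checks."""
    return hashlib.sha256(coalvi_csv_text().encode("utf-8")).hexdigest()


def coalvi() -> SystemLedger:
    """The beef-farm consortium validation ledger (10^3 t C per year)."""
    with resources.as_file(_DATA / "coalvi_table1.csv") as path:
        ledger = read_ledger(path)
    meta = yaml.safe_load((_DATA / "coalvi_config.yaml").read_text(encoding="utf-8"))
    ledger.system_name = meta["system_name"]
    ledger.period = meta["period"]
    ledger.canonical_unit = meta["canonical_unit"]
    ledger.functional_units = [
        FunctionalUnit(fu["name"], float(fu["quantity"]), fu["units"])
        for fu in meta["functional_units"]
    ]
    return ledger
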