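"""Systemic carbon balance, site storage and derived indices.

The net systemic balance is total inputs minus total outputs across the
system boundary; internal transfers cancel by construction. A positive
balance means the system is accumulating carbon over the period, negative
means it is depleting its stocks, zero is equilibrium. The balance is
complemented by:

* the air-site change — the system's net exchange with the atmosphere,
  reported negative when the system removes carbon from the air;
* per-site gross storage — carbon accumulated in each system site's biomass
  pool before market exports, computed as biogenic inflows minus biogenic
  non-export outflows (fossil pass-through fluxes are excluded from the
  pools; this convention is reconstructed, see the methods note);
* the efficiency index (balance / inputs, dimensionless, sign follows the
  balance) and the intensity index (inputs per functional unit);
* per-functional-unit tables, every total divided by the FU denominator.

A reconciliation record verifies two accounting identities on any report:
global conservation (each flux leaves one site and enters another, so the
signed change summed over all five sites is identically zero) and the
decomposition of the balance into storage, exports and the fossil
pass-through.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .model import (
    FluxCategory,
    FunctionalUnit,
    Site,
    SystemLedger,
    SYSTEM_SITES,
    require_valid,
)


class UndefinedIndexError(ZeroDivisionError):
    """An index whose denominator is zero or negative was requested."""


@dataclass
class BalanceReport:
    """Computed totals, storage and indices for one ledger.

    All carbon amounts are in the ledger's canonical unit. ``air_change``
    is negative when the system is a net remover of atmospheric carbon.
    ``efficiency`` is None when the ledger has no inputs. ``intensity`` and
    ``per_fu`` are keyed by functional-unit name.
    """

    system_name: str
    period: str
    unit: str
    total_inputs: float
    total_outputs: float
    balance: float
    site_storage: dict[Site, float] = field(default_factory=dict)
    air_change: float = 0.0
    efficiency: float | None = None
    intensity: dict[str, float] = field(default_factory=dict)
    per_fu: dict[str, pd.DataFrame] = field(default_factory=dict)
    ledger: SystemLedger | None = None  # source ledger, for tabular rendering


def _sum(values) -> float:
    return math.fsum(values)


def air_site_change(ledger: SystemLedger) -> float:
    """Net change of the air site: releases to air minus uptake from air."""
    into_air = _sum(f.amount_c for f in ledger.fluxes if f.sink is Site.AIR)
    from_air = _sum(f.amount_c for f in ledger.fluxes if f.source is Site.AIR)
    return into_air - from_air


def site_gross_storage(ledger: SystemLedger, site: Site) -> float:
    """Gross carbon stored in a system site's biomass pool over the period.

    Biogenic inflows into the site minus biogenic outflows to other system
    sites or to air. Market exports (sink = external) stay in the pool until
    sold and are handled separately in the reconciliation; fossil-flagged
    fluxes (fuel and its combustion, grid electricity) never enter a
    biomass pool.
    """
    site = Site(site)
    if site not in SYSTEM_SITES:
        raise ValueError(f"storage is defined for system sites only, not {site.value}")
    inflow = _sum(
        f.amount_c for f in ledger.fluxes if f.sink is site and not f.fossil
    )
    outflow = _sum(
        f.amount_c
        for f in ledger.fluxes
        if f.source is site and not f.fossil and f.sink is not Site.EXTERNAL
    )
    return inflow - outflow


def efficiency(report: BalanceReport) -> float:
    """Carbon efficiency: balance over total inputs (sign follows the balance)."""
    if not report.total_inputs > 0:
        raise UndefinedIndexError("efficiency undefined: total inputs are zero")
    return report.balance / report.total_inputs


def intensity(report: BalanceReport, fu: FunctionalUnit) -> float:
    """Carbon intensity: total inputs per functional unit."""
    if not fu.quantity > 0:
        raise UndefinedIndexError(f"intensity undefined for FU {fu.name!r} with quantity {fu.quantity}")
    return report.total_inputs / fu.quantity


def per_fu_table(
    ledger: SystemLedger, report: BalanceReport, fu: FunctionalUnit
) -> pd.DataFrame:
    """Every flux, storage and summary value divided by the FU denominator.

    Rows carry the signed reporting convention: inputs positive, outputs
    negative; internal fluxes are shown once with their source→sink
    direction and a positive magnitude. Columns: ``kind``, ``label``,
    ``total`` (canonical unit) and ``per_fu`` (total / fu.quantity).
    """
    if not fu.quantity > 0:
        raise UndefinedIndexError(f"per-FU table undefined for FU {fu.name!r}")
    rows: list[dict] = []
    for site in (Site.ANIMAL, Site.PLANT, Site.SOIL):
        rows.append(
            {
                "kind": "storage",
                "label": f"C stored: {site.value}",
                "total": report.site_storage.get(site, 0.0),
            }
        )
    rows.append({"kind": "storage", "label": "C stored: air", "total": report.air_change})
    sign = {FluxCategory.INPUT: 1.0, FluxCategory.OUTPUT: -1.0, FluxCategory.INTERNAL: 1.0}
    for f in ledger.fluxes:
        rows.append(
            {
                "kind": f"flux ({f.category.value})",
                "label": f.label,
                "total": sign[f.category] * f.amount_c,
            }
        )
    rows.append({"kind": "summary", "label": "total inputs", "total": report.total_inputs})
    rows.append({"kind": "summary", "label": "total outputs", "total": -report.total_outputs})
    rows.append({"kind": "summary", "label": "balance (inputs - outputs)", "total": report.balance})
    table = pd.DataFrame(rows, columns=["kind", "label", "total"])
    table["per_fu"] = table["total"] / fu.quantity
    return table


def compute_balance(ledger: SystemLedger) -> BalanceReport:
    """Validate the ledger and compute the full balance report.

    Raises :class:`~carbonledger.model.LedgerValidationError` if the ledger
    breaks any invariant; otherwise fills totals, balance, per-site storage,
    air change, and — where defined — efficiency, intensity and per-FU
    tables for every functional unit on the ledger.
    """
    require_valid(ledger)
    total_in = _sum(f.amount_c for f in ledger.by_category(FluxCategory.INPUT))
    total_out = _sum(f.amount_c for f in ledger.by_category(FluxCategory.OUTPUT))
    report = BalanceReport(
        system_name=ledger.system_name,
        period=ledger.period,
        unit=ledger.canonical_unit,
        total_inputs=total_in,
        total_outputs=total_out,
        balance=total_in - total_out,
        ledger=ledger,
    )
    report.site_storage = {
        site: site_gross_storage(ledger, site)
        for site in (Site.ANIMAL, Site.PLANT, Site.SOIL)
    }
    report.air_change = air_site_change(ledger)
    report.efficiency = efficiency(report) if total_in > 0 else None
    for fu in ledger.functional_units:
        report.intensity[fu.name] = intensity(report, fu)
        report.per_fu[fu.name] = per_fu_table(ledger, report, fu)
    return report


RECONCILE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class Reconciliation:
    """Residuals of the accounting identities, with a pass/fail verdict.

    ``conservation_residual`` — signed net change summed over all five
    sites; zero for every ledger since each flux leaves one site and enters
    another. ``decomposition_residual`` — balance minus (Σ site storage −
    exports + fossil inputs − fossil outputs). Both are compared at
    ``tolerance`` relative to the balance magnitude.
    """

    conservation_residual: float
    decomposition_residual: float
    tolerance: float
    passed: bool


def reconcile(report: BalanceReport, ledger: SystemLedger) -> Reconciliation:
    site_change: dict[Site, float] = {s: 0.0 for s in Site}
    for f in ledger.fluxes:
        site_change[f.sink] += f.amount_c
        site_change[f.source] -= f.amount_c
    conservation = _sum(site_change.values())

    storage_total = _sum(report.site_storage.values())
    # exports drawn from the biomass pools; fossil exports (rare) are already
    # counted in the fossil-output term
    exports = _sum(
        f.amount_c for f in ledger.fluxes if f.sink is Site.EXTERNAL and not f.fossil
    )
    fossil_in = _sum(
        f.amount_c
        for f in ledger.by_category(FluxCategory.INPUT)
        if f.fossil
    )
    fossil_out = _sum(
        f.amount_c
        for f in ledger.by_category(FluxCategory.OUTPUT)
        if f.fossil
    )
    decomposition = report.balance - (storage_total - exports + fossil_in - fossil_out)

    scale = max(1.0, abs(report.balance))
    passed = (
        abs(conservation) <= RECONCILE_TOLERANCE * scale
        and abs(decomposition) <= RECONCILE_TOLERANCE * scale
    )
    return Reconciliation(conservation, decomposition, RECONCILE_TOLERANCE, passed)
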