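"""Flux-network data model for systemic carbon accounting.

A production system is modelled as five carbon *sites*: three system sites
(``animal``, ``plant``, ``soil``) holding the system's carbon pools, and two
boundary sites (``air``, the atmosphere, and ``external``, the market/outside
world). Every material or energy flow, once expressed as carbon mass, is a
directed flux between two sites. The flux category — input, output or
internal — is fully determined by which side of the system boundary its
endpoints sit on, and the whole-system balance follows from inputs minus
outputs, with internal transfers cancelling.

Amounts are stored as nonnegative magnitudes; direction is carried by the
(source, sink) pair, and the conventional +/− sign of inputs/outputs is
applied only when reports are rendered.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class Site(str, enum.Enum):
    """A carbon pool of the system or of its surroundings."""

    ANIMAL = "animal"
    PLANT = "plant"
    SOIL = "soil"
    AIR = "air"
    EXTERNAL = "external"

    @property
    def is_system(self) -> bool:
        return self in SYSTEM_SITES

    @property
    def is_boundary(self) -> bool:
        return self in BOUNDARY_SITES


SYSTEM_SITES = frozenset({Site.ANIMAL, Site.PLANT, Site.SOIL})
BOUNDARY_SITES = frozenset({Site.AIR, Site.EXTERNAL})


class FluxCategory(str, enum.Enum):
    INPUT = "input"
    OUTPUT = "output"
    INTERNAL = "internal"


class Sector(str, enum.Enum):
    """Productive sector a flux is attributed to — reporting metadata only."""

    ANIMAL = "animal"
    PLANT = "plant"
    SOIL = "soil"


class InvalidTopologyError(ValueError):
    """Raised for a site pair that carries no admissible flux."""


def derive_category(source: Site, sink: Site) -> FluxCategory:
    """Category of a flux from its endpoints.

    boundary → system is an input, system → boundary an output,
    system → system an internal transfer. A flux between two boundary
    sites never crosses the system and is rejected, as is a self-loop.
    """
    source, sink = Site(source), Site(sink)
    if source == sink:
        raise InvalidTopologyError(f"flux source and sink coincide: {source.value}")
    if source.is_boundary and sink.is_boundary:
        raise InvalidTopologyError(
            f"flux {source.value}->{sink.value} does not cross the system boundary"
        )
    if source.is_boundary:
        return FluxCategory.INPUT
    if sink.is_boundary:
        return FluxCategory.OUTPUT
    return FluxCategory.INTERNAL


@dataclass(frozen=True)
class FluxRecord:
    """One directed carbon flow between two sites over the accounting period.

    ``amount_c`` is a nonnegative carbon mass in the ledger's canonical unit
    (tonnes C unless the ledger declares a scale). ``variation_pct`` is the
    most probable half-range of variation of the amount, in percent.
    ``fossil`` marks carbon of fossil origin (fuel, grid electricity), which
    is excluded from biomass storage pools.
    """

    id: str
    label: str
    sector: Sector
    source: Site
    sink: Site
    category: FluxCategory
    material: str
    amount_c: float
    variation_pct: float | None = None
    fossil: bool = False

    @classmethod
    def make(
        cls,
        id: str,
        label: str,
        sector: Sector | str,
        source: Site | str,
        sink: Site | str,
        material: str,
        amount_c: float,
        variation_pct: float | None = None,
        fossil: bool = False,
    ) -> "FluxRecord":
        """Build a record with the category derived from its endpoints."""
        source, sink = Site(source), Site(sink)
        return cls(
            id=id,
            label=label,
            sector=Sector(sector),
            source=source,
            sink=sink,
            category=derive_category(source, sink),
            material=material,
            amount_c=float(amount_c),
            variation_pct=None if variation_pct is None else float(variation_pct),
            fossil=bool(fossil),
        )


@dataclass(frozen=True)
class FunctionalUnit:
    """Normalisation denominator for reporting (e.g. hectares, t slaughtered LW)."""

    name: str
    quantity: float
    units: str

    def __post_init__(self) -> None:
        if not self.quantity > 0:
            raise ValueError(f"functional unit {self.name!r} quantity must be > 0")


@dataclass
class SystemLedger:
    """A validated collection of carbon fluxes plus system metadata.

    ``canonical_unit`` names the unit every ``amount_c`` is expressed in;
    the engine itself only requires that it is uniform within a ledger
    (the packaged validation case uses 10^3 t C, matching the source table).
    """

    system_name: str
    period: str = "1 year"
    fluxes: list[FluxRecord] = field(default_factory=list)
    functional_units: list[FunctionalUnit] = field(default_factory=list)
    canonical_unit: str = "t C"

    def __iter__(self):
        return iter(self.fluxes)

    def __len__(self) -> int:
        return len(self.fluxes)

    def by_category(self, category: FluxCategory) -> list[FluxRecord]:
        category = FluxCategory(category)
        return [f for f in self.fluxes if f.category is category]

    def functional_unit(self, name: str) -> FunctionalUnit:
        for fu in self.functional_units:
            if fu.name == name:
                return fu
        raise KeyError(f"no functional unit named {name!r}")


@dataclass(frozen=True)
class Violation:
    """A broken ledger invariant, attributed to a flux id (or the ledger)."""

    flux_id: str | None
    rule: str
    message: str

    def __str__(self) -> str:
        where = self.flux_id if self.flux_id is not None else "<ledger>"
        return f"[{where}] {self.rule}: {self.message}"


def validate_ledger(ledger: SystemLedger) -> list[Violation]:
    """Check every ledger invariant; return the (possibly empty) violation list.

    Violations are collected, never raised, so a report can name every
    offending flux at once. An empty list means the ledger is valid.
    """
    violations: list[Violation] = []
    seen: dict[str, int] = {}
    for rec in ledger.fluxes:
        if rec.id in seen:
            violations.append(
                Violation(rec.id, "unique-id", "flux id occurs more than once")
            )
        seen[rec.id] = seen.get(rec.id, 0) + 1

        if rec.source == rec.sink:
            violations.append(
                Violation(rec.id, "topology", f"source equals sink ({rec.source.value})")
            )
            continue
        if rec.source.is_boundary and rec.sink.is_boundary:
            violations.append(
                Violation(
                    rec.id,
                    "topology",
                    f"{rec.source.value}->{rec.sink.value} does not cross the boundary",
                )
            )
            continue
        derived = derive_category(rec.source, rec.sink)
        if rec.category is not derived:
            violations.append(
                Violation(
                    rec.id,
                    "category",
                    f"declared {rec.category.value!r} but "
                    f"{rec.source.value}->{rec.sink.value} derives {derived.value!r}",
                )
            )
        if not rec.amount_c >= 0:
            violations.append(
                Violation(rec.id, "amount", f"amount_c must be >= 0, got {rec.amount_c}")
            )
        if rec.variation_pct is not None and not rec.variation_pct >= 0:
            violations.append(
                Violation(
                    rec.id,
                    "variation",
                    f"variation_pct must be >= 0, got {rec.variation_pct}",
                )
            )
    return violations


class LedgerValidationError(ValueError):
    """A ledger failed validation where a valid one was required."""

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        super().__init__(
            "invalid ledger: " + "; ".join(str(v) for v in self.violations)
        )


def require_valid(ledger: SystemLedger) -> SystemLedger:
    violations = validate_ledger(ledger)
    if violations:
        raise LedgerValidationError(violations)
    return ledger


# merge key for aggregation: everything that identifies "the same kind of flux"
def _merge_key(rec: FluxRecord):
    return (rec.source, rec.sink, rec.category, rec.material, rec.sector, rec.fossil)


def aggregate(ledgers: Iterable[SystemLedger]) -> SystemLedger:
    """Merge ledgers of the same period into one.

    Homogeneous records — identical (source, sink, category, material,
    sector, fossil) — are summed; the merged variation range is the
    amount-weighted mean of the members that carry one. Records with no
    counterpart pass through unchanged. Periods must agree; merged ids are
    re-labelled sequentially.
    """
    ledgers = list(ledgers)
    if not ledgers:
        return SystemLedger(system_name="aggregate", fluxes=[])
    periods = {lg.period for lg in ledgers}
    if len(periods) > 1:
        raise ValueError(f"cannot aggregate ledgers with mixed periods: {sorted(periods)}")
    units = {lg.canonical_unit for lg in ledgers}
    if len(units) > 1:
        raise ValueError(f"cannot aggregate ledgers with mixed units: {sorted(units)}")

    merged: dict[tuple, dict] = {}
    order: list[tuple] = []
    for lg in ledgers:
        for rec in lg.fluxes:
            key = _merge_key(rec)
            if key not in merged:
                merged[key] = {
                    "proto": rec,
                    "amount": 0.0,
                    "var_weight": 0.0,  # sum amount*variation over members with one
                    "var_amount": 0.0,  # sum amount over members with one
                }
                order.append(key)
            slot = merged[key]
            slot["amount"] += rec.amount_c
            if rec.variation_pct is not None:
                slot["var_weight"] += rec.amount_c * rec.variation_pct
                slot["var_amount"] += rec.amount_c

    fluxes: list[FluxRecord] = []
    for i, key in enumerate(order, start=1):
        slot = merged[key]
        if slot["var_amount"] > 0:
            variation = slot["var_weight"] / slot["var_amount"]
        elif slot["proto"].variation_pct is not None and slot["amount"] == 0:
            variation = slot["proto"].variation_pct
        else:
            variation = None
        fluxes.append(
            replace(
                slot["proto"],
                id=f"f{i:03d}",
                amount_c=slot["amount"],
                variation_pct=variation,
            )
        )

    fus: list[FunctionalUnit] = []
    seen_fu: set[str] = set()
    for lg in ledgers:
        for fu in lg.functional_units:
            if fu.name not in seen_fu:
                fus.append(fu)
                seen_fu.add(fu.name)

    name = " + ".join(dict.fromkeys(lg.system_name for lg in ledgers))
    return SystemLedger(
        system_name=name,
        period=ledgers[0].period,
        fluxes=fluxes,
        functional_units=fus,
        canonical_unit=ledgers[0].canonical_unit,
    )
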