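"""Material → carbon conversion coefficients and operations.

Material and energy flows are turned into carbon mass with stoichiometric or
empirical coefficients: a dimensionless C mass fraction for solids and gases
(e.g. 12.0107/44.0095 ≈ 0.27291 for CO2), grams of C per litre for liquid
fuels, and kilograms of C per kWh for grid electricity (country-specific,
never defaulted). The registry ships seeded with the standard livestock-farm
coefficient set; overrides and additions carry a provenance string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal
import warnings

# CODATA-style standard atomic masses (g/mol)
ATOMIC_MASS = {"C": 12.0107, "O": 15.9994, "H": 1.00794, "N": 14.0067}

Basis = Literal["mass_fraction", "c_per_volume", "c_per_energy"]

# closed unit set; factors to the canonical base of each unit class
_MASS_TO_TONNES = {"g": 1e-6, "kg": 1e-3, "t": 1.0}
_VOLUME_TO_LITRES = {"L": 1.0, "m3": 1000.0}
_ENERGY_TO_KWH = {"kWh": 1.0}

_BASIS_FOR_UNIT = {
    **{u: "mass_fraction" for u in _MASS_TO_TONNES},
    **{u: "c_per_volume" for u in _VOLUME_TO_LITRES},
    **{u: "c_per_energy" for u in _ENERGY_TO_KWH},
}


class UnknownMaterialError(KeyError):
    pass


class UnitError(ValueError):
    pass


class ConfigurationRequiredError(ValueError):
    """A coefficient that must be user-supplied has not been configured."""


@dataclass(frozen=True)
class CoefficientEntry:
    """One material → carbon conversion rule.

    ``value`` is a C mass fraction for ``mass_fraction`` basis, g C per litre
    for ``c_per_volume``, kg C per kWh for ``c_per_energy``. ``value_range``
    bounds materials whose fraction depends on context (live weight by breed).
    """

    material: str
    basis: Basis
    value: float | None
    source: str = ""
    value_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.value is not None:
            if self.basis == "mass_fraction" and not (0 < self.value <= 1):
                raise ValueError(
                    f"{self.material}: mass fraction must lie in (0, 1], got {self.value}"
                )
            if self.basis != "mass_fraction" and not self.value > 0:
                raise ValueError(f"{self.material}: coefficient must be > 0")
        if self.value_range is not None:
            low, high = self.value_range
            if self.value is not None and not (low <= self.value <= high):
                raise ValueError(
                    f"{self.material}: value {self.value} outside range [{low}, {high}]"
                )


def _default_entries() -> dict[str, CoefficientEntry]:
    """The seeded coefficient set for a livestock farm system.

    The printed literature values are stored verbatim (CH4 keeps 0.74882
    even though the molar-mass ratio gives 0.74869; see
    :func:`check_stoichiometry`). Live weight has no point value until a
    breed-specific fraction is configured; electricity is country-specific
    and always user-supplied.
    """
    e = CoefficientEntry
    return {
        "co2": e("co2", "mass_fraction", 0.27291, "stoichiometry, CO2"),
        "ch4": e("ch4", "mass_fraction", 0.74882, "stoichiometry, CH4"),
        "urea": e("urea", "mass_fraction", 0.19998, "stoichiometry, urea fertiliser CH4N2O"),
        "protein": e("protein", "mass_fraction", 0.46, "literature, crude protein"),
        "fat": e("fat", "mass_fraction", 0.70, "literature, fats"),
        "carbohydrate": e("carbohydrate", "mass_fraction", 0.40, "stoichiometry, CnH2nOn"),
        "urine": e("urine", "mass_fraction", 0.36, "literature, urine"),
        "plant_material": e(
            "plant_material",
            "mass_fraction",
            0.50,
            "average plant molecular formula CH1.44O0.66",
        ),
        "live_weight": e(
            "live_weight",
            "mass_fraction",
            None,
            "breed-specific, to be configured",
            value_range=(0.15, 0.20),
        ),
        "oil": e("oil", "c_per_volume", 723.2, "oil (fuel), density-based"),
        "electricity": e(
            "electricity", "c_per_energy", None, "national electricity mix, to be configured"
        ),
    }


@dataclass
class CoefficientRegistry:
    """Mapping material tag → conversion rule, seeded with the standard set."""

    entries: dict[str, CoefficientEntry] = field(default_factory=_default_entries)

    def __contains__(self, material: str) -> bool:
        return material in self.entries

    def get(self, material: str) -> CoefficientEntry:
        try:
            return self.entries[material]
        except KeyError:
            raise UnknownMaterialError(
                f"no conversion coefficient registered for material {material!r}"
            ) from None

    def set(
        self,
        material: str,
        basis: Basis,
        value: float,
        source: str = "user override",
    ) -> CoefficientEntry:
        """Register or override a coefficient, recording its provenance."""
        prev = self.entries.get(material)
        value_range = prev.value_range if prev is not None else None
        if (
            material == "live_weight"
            and value_range is not None
            and not (value_range[0] <= value <= value_range[1])
        ):
            warnings.warn(
                f"live_weight fraction {value} outside the usual breed range "
                f"[{value_range[0]}, {value_range[1]}]",
                stacklevel=2,
            )
            value_range = None  # keep the override but drop the violated bound
        entry = CoefficientEntry(material, basis, value, source, value_range)
        self.entries[material] = entry
        return entry

    def set_live_weight_fraction(self, fraction: float, source: str = "breed-specific") -> None:
        self.set("live_weight", "mass_fraction", fraction, source)

    def set_electricity_factor(self, kg_c_per_kwh: float, source: str = "national inventory") -> None:
        self.set("electricity", "c_per_energy", kg_c_per_kwh, source)


def to_carbon(
    amount: float,
    unit: str,
    material: str,
    registry: CoefficientRegistry | None = None,
) -> float:
    """Convert an amount of material to tonnes of carbon.

    ``unit`` must belong to the closed set {g, kg, t, L, m3, kWh} and its
    class (mass/volume/energy) must match the basis of the registered
    coefficient for ``material``.
    """
    if registry is None:
        registry = CoefficientRegistry()
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount}")
    if unit not in _BASIS_FOR_UNIT:
        raise UnitError(f"unknown unit {unit!r}; expected one of {sorted(_BASIS_FOR_UNIT)}")
    entry = registry.get(material)
    if _BASIS_FOR_UNIT[unit] != entry.basis:
        raise UnitError(
            f"unit {unit!r} is {_BASIS_FOR_UNIT[unit]}-basis but {material!r} "
            f"is registered on {entry.basis} basis"
        )
    if entry.value is None:
        raise ConfigurationRequiredError(
            f"material {material!r} requires an explicitly configured coefficient "
            f"({entry.source})"
        )
    if entry.basis == "mass_fraction":
        return amount * _MASS_TO_TONNES[unit] * entry.value
    if entry.basis == "c_per_volume":
        # value in g C per litre
        return amount * _VOLUME_TO_LITRES[unit] * entry.value * 1e-6
    # c_per_energy: value in kg C per kWh
    return amount * _ENERGY_TO_KWH[unit] * entry.value * 1e-3


def energy_to_carbon(kwh: float, factor_kg_c_per_kwh: float) -> float:
    """Electricity use to tonnes of carbon via a user-supplied emission factor."""
    if kwh < 0:
        raise ValueError(f"kwh must be >= 0, got {kwh}")
    if factor_kg_c_per_kwh is None or not factor_kg_c_per_kwh > 0:
        raise ConfigurationRequiredError(
            "electricity conversion needs a positive kg C/kWh factor from the "
            "national emission inventory"
        )
    return kwh * factor_kg_c_per_kwh / 1000.0


def carbon_mass_fraction(formula: dict[str, float]) -> float:
    """Exact C mass fraction of a molecular formula, from standard atomic masses."""
    molar = sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    return ATOMIC_MASS["C"] * formula.get("C", 0) / molar


_GAS_FORMULAE = {
    "co2": {"C": 1, "O": 2},
    "ch4": {"C": 1, "H": 4},
    "urea": {"C": 1, "H": 4, "N": 2, "O": 1},
}

STOICHIOMETRY_TOLERANCE = 2e-4


@dataclass(frozen=True)
class StoichiometryCheck:
    material: str
    registry_value: float
    exact_value: float
    deviation: float
    flagged: bool  # deviation exceeds the tolerance


def check_stoichiometry(
    registry: CoefficientRegistry | None = None,
    tolerance: float = STOICHIOMETRY_TOLERANCE,
) -> list[StoichiometryCheck]:
    """Cross-check registered gas coefficients against exact molar-mass ratios.

    The registry keeps literature values verbatim; this check only reports
    the deviation of each gas coefficient from the value computed from
    standard atomic masses, flagging deviations above ``tolerance``.
    """
    if registry is None:
        registry = CoefficientRegistry()
    report = []
    for material, formula in _GAS_FORMULAE.items():
        if material not in registry:
            continue
        entry = registry.get(material)
        if entry.value is None or entry.basis != "mass_fraction":
            continue
        exact = carbon_mass_fraction(formula)
        dev = abs(entry.value - exact)
        report.append(
            StoichiometryCheck(material, entry.value, exact, dev, dev > tolerance)
        )
    return report
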