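"""Derived carbon quantities computed from raw herd and field data.

The centrepiece is the enteric-emission-by-difference estimator: direct
measurement of enteric gases is unreliable (tracer-gas and open-path-laser
techniques capture methane but not carbon dioxide), so enteric C is instead
closed out of the animal carbon budget — feed C in, minus C retained as
weight gain and every other measured C output. The residual is the CO2 + CH4
lost through eructation, and the six-way partition of feed carbon closes
exactly by construction.

The remaining helpers cover the generic coefficient-based derivations
(crop residues from yield, manure from excretion rates, fuel per field
operation, ...) with a provenance trace, and the descriptive-statistics
estimate of a variable's most probable variation half-range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


class InconsistentAccountError(ValueError):
    """The animal account's outputs exceed its feed carbon input."""


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class AnimalCarbonAccount:
    """Carbon budget of a herd over the accounting period, all in t C.

    ``lw_retention_c`` is carbon retained as live-weight gain; calves leaving
    the herd are booked separately, not inside retention. The account is
    consistent only if the named outputs do not exceed the feed input —
    the remainder is the enteric loss.
    """

    feed_intake_c: float
    lw_retention_c: float
    milk_c: float
    calves_c: float
    respiration_c: float
    excreta_c: float

    def __post_init__(self) -> None:
        for name in (
            "feed_intake_c",
            "lw_retention_c",
            "milk_c",
            "calves_c",
            "respiration_c",
            "excreta_c",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def non_enteric_outputs_c(self) -> float:
        return (
            self.lw_retention_c
            + self.milk_c
            + self.calves_c
            + self.respiration_c
            + self.excreta_c
        )


def enteric_by_difference(account: AnimalCarbonAccount) -> float:
    """Enteric gas carbon (CO2 + CH4) as the closure of the animal C budget.

    Returns feed C minus retention, milk, calves, respiration and excreta C.
    A negative difference means the account is inconsistent (outputs exceed
    intake) and raises, naming the shortfall.
    """
    enteric = account.feed_intake_c - account.non_enteric_outputs_c
    if enteric < 0:
        raise InconsistentAccountError(
            f"non-enteric outputs ({account.non_enteric_outputs_c:g} t C) exceed "
            f"feed intake ({account.feed_intake_c:g} t C) by {-enteric:g} t C"
        )
    return enteric


@dataclass(frozen=True)
class DerivationTrace:
    """Provenance of one coefficient-based derivation."""

    label: str
    raw_amount: float
    coefficient: float
    derived: float
    source: str = ""


@dataclass
class DerivationLog:
    """Accumulates derivation traces for the provenance table of a report."""

    traces: list[DerivationTrace] = field(default_factory=list)

    def record(self, trace: DerivationTrace) -> None:
        self.traces.append(trace)


def coefficient_product(
    raw_amount: float,
    coefficient: float,
    label: str = "",
    source: str = "",
    log: DerivationLog | None = None,
) -> float:
    """raw_amount × coefficient, with the derivation recorded when a log is given.

    Used for the many sector-specific derivations (residue-to-grain ratios,
    excretion rates, fuel per operation) whose coefficients come from the
    analyst, not from this package.
    """
    if not raw_amount >= 0:
        raise ValueError(f"raw_amount must be finite and >= 0, got {raw_amount}")
    if not coefficient >= 0:
        raise ValueError(f"coefficient must be finite and >= 0, got {coefficient}")
    derived = raw_amount * coefficient
    if log is not None:
        log.record(DerivationTrace(label, raw_amount, coefficient, derived, source))
    return derived


def variation_range(observations: Iterable[float], mode: str = "half_range") -> float:
    """Most probable symmetric variation half-range, as a percent of the mean.

    ``half_range`` (default) returns 100·(max − min)/(2·mean): half the
    observed spread relative to the level. ``cv`` instead returns the percent
    coefficient of variation (sample standard deviation / mean). Needs at
    least two observations and a nonzero mean.
    """
    obs: Sequence[float] = list(observations)
    if len(obs) < 2:
        raise InsufficientDataError(
            f"need at least 2 observations to estimate a range, got {len(obs)}"
        )
    mean = sum(obs) / len(obs)
    if mean == 0:
        raise InsufficientDataError("mean of observations is zero; range undefined")
    if mode == "half_range":
        return 100.0 * (max(obs) - min(obs)) / (2.0 * abs(mean))
    if mode == "cv":
        var = sum((x - mean) ** 2 for x in obs) / (len(obs) - 1)
        return 100.0 * var**0.5 / abs(mean)
    raise ValueError(f"unknown mode {mode!r}; expected 'half_range' or 'cv'")
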