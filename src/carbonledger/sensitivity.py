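"""Two-way sensitivity analysis of the systemic carbon balance.

Flux measurements in farm systems carry large uncertainty, so the headline
balance is stress-tested by perturbing the pooled input and output totals.
Each category's pooled variation is the amount-weighted mean of its
components' most probable variation half-ranges; the two pooled percentages
(optionally rounded to the nearest integer) then span a grid of scenarios —
the four corners (inputs up/down × outputs up/down) plus the centre — over
which the balance is recomputed. The verdict is *sign-robust* when every
scenario's balance shares the sign of the central balance: the qualitative
conclusion (the system accumulates or depletes carbon) survives the
measurement uncertainty. Internal fluxes cancel in the balance and are left
unperturbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import FluxCategory, SystemLedger, require_valid
from .balance import _sum


class IncompleteVariationError(ValueError):
    """Some fluxes of the category carry no variation range."""

    def __init__(self, missing_ids: list[str], category: FluxCategory):
        self.missing_ids = missing_ids
        super().__init__(
            f"cannot pool the {category.value} variation: fluxes without "
            f"variation_pct: {', '.join(missing_ids)}"
        )


class InvalidCategoryError(ValueError):
    pass


def weighted_variation(ledger: SystemLedger, category: FluxCategory) -> float:
    """Pooled variation of a category: amount-weighted mean of component ranges.

    Every flux of the category must carry a ``variation_pct``; internal
    fluxes have no pooled variation (they do not enter the balance).
    """
    category = FluxCategory(category)
    if category is FluxCategory.INTERNAL:
        raise InvalidCategoryError("internal fluxes do not enter the balance; no pooled variation")
    fluxes = ledger.by_category(category)
    missing = [f.id for f in fluxes if f.variation_pct is None]
    if missing:
        raise IncompleteVariationError(missing, category)
    total = _sum(f.amount_c for f in fluxes)
    if total == 0:
        return 0.0
    return _sum(f.amount_c * f.variation_pct for f in fluxes) / total


def round_variation(value: float, mode: str = "nearest-integer") -> float:
    """Round a pooled variation percentage for use in the scenario grid.

    ``nearest-integer`` rounds half away from zero (10.4 → 10, 9.9 → 10,
    10.5 → 11); ``none`` returns the value unchanged.
    """
    if value < 0:
        raise ValueError(f"variation must be >= 0, got {value}")
    if mode == "none":
        return value
    if mode == "nearest-integer":
        return float(math.floor(value + 0.5))
    raise ValueError(f"unknown rounding mode {mode!r}")


@dataclass
class SensitivityResult:
    """Balances over the perturbation grid, with worst/best case and verdict.

    ``grid`` maps (input multiplier, output multiplier) → balance.
    ``sign_robust`` is True iff every grid balance strictly shares the sign
    of the centre balance (a zero anywhere, or a centre of zero with any
    perturbation, is not robust).
    """

    delta_in_pct: float
    delta_out_pct: float
    centre: float
    grid: dict[tuple[float, float], float] = field(default_factory=dict)
    worst_case: float = 0.0
    best_case: float = 0.0
    sign_robust: bool = False


def _perturbed_balance(
    total_in: float, total_out: float, in_mult: float, out_mult: float
) -> float:
    return total_in * in_mult - total_out * out_mult


def two_way_sensitivity(
    ledger: SystemLedger,
    delta_in_pct: float,
    delta_out_pct: float,
    grid_points: int = 2,
) -> SensitivityResult:
    """Recompute the balance with inputs scaled by 1±δin and outputs by 1±δout.

    The multipliers are uniform within each category — the analysis uses one
    pooled variation per side of the boundary, not per-flux ranges. With
    ``grid_points=2`` the grid is the four corners plus the centre;
    larger values refine each axis to that many equally spaced multipliers
    (the centre is always included).
    """
    if delta_in_pct < 0 or delta_out_pct < 0:
        raise ValueError("perturbation deltas must be >= 0")
    if grid_points < 2:
        raise ValueError("grid needs at least the two extreme multipliers per axis")
    require_valid(ledger)
    total_in = _sum(f.amount_c for f in ledger.by_category(FluxCategory.INPUT))
    total_out = _sum(f.amount_c for f in ledger.by_category(FluxCategory.OUTPUT))

    din, dout = delta_in_pct / 100.0, delta_out_pct / 100.0
    in_mults = [1 - din + 2 * din * k / (grid_points - 1) for k in range(grid_points)]
    out_mults = [1 - dout + 2 * dout * k / (grid_points - 1) for k in range(grid_points)]

    centre = _perturbed_balance(total_in, total_out, 1.0, 1.0)
    grid: dict[tuple[float, float], float] = {(1.0, 1.0): centre}
    for im in in_mults:
        for om in out_mults:
            grid[(im, om)] = _perturbed_balance(total_in, total_out, im, om)

    balances = list(grid.values())
    worst, best = min(balances), max(balances)
    sign_robust = (
        centre != 0 and all(math.copysign(1.0, b) == math.copysign(1.0, centre) and b != 0 for b in balances)
    )
    return SensitivityResult(
        delta_in_pct=delta_in_pct,
        delta_out_pct=delta_out_pct,
        centre=centre,
        grid=grid,
        worst_case=worst,
        best_case=best,
        sign_robust=sign_robust,
    )


def sensitivity_from_variation(
    ledger: SystemLedger, rounding: str = "nearest-integer"
) -> SensitivityResult:
    """Two-way analysis with deltas pooled from the ledger's own variation data."""
    din = round_variation(weighted_variation(ledger, FluxCategory.INPUT), rounding)
    dout = round_variation(weighted_variation(ledger, FluxCategory.OUTPUT), rounding)
    return two_way_sensitivity(ledger, din, dout)
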