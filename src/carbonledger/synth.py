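"""Seeded synthetic flux ledgers for testing and benchmarking.

The generator emulates the shape of a multi-site farm carbon ledger: a mix
of boundary-crossing inputs and outputs and internal transfers among the
animal, plant and soil pools, with right-skewed flux magnitudes (a few large
fluxes such as net plant exchange dominate many small ones) and per-flux
variation half-ranges in the band typically reported for farm records.
Categories are consistent with the endpoints by construction, so every
generated ledger validates. Fossil-flagged fluxes only occur where fossil
carbon occurs in practice: entering from the market (fuel) or leaving to
the air (combustion, grid electricity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    FluxCategory,
    FluxRecord,
    FunctionalUnit,
    Sector,
    Site,
    SystemLedger,
)

_SYSTEM = [Site.ANIMAL, Site.PLANT, Site.SOIL]
_BOUNDARY = [Site.AIR, Site.EXTERNAL]

_MATERIALS = ["plant_material", "co2", "ch4", "protein", "fat", "carbohydrate", "custom"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic ledger generator.

    ``category_mix`` gives the probabilities of drawing an input / output /
    internal flux. Amounts are log-normal with median ``exp(amount_log_mean)``
    tonnes C and log-sd ``amount_log_sigma``; variation half-ranges are
    uniform on ``variation_range_pct``. ``fossil_prob`` is the chance that an
    eligible flux (external source or air sink) is fossil carbon.
    """

    category_mix: tuple[float, float, float] = (0.3, 0.4, 0.3)
    amount_log_mean: float = 3.0  # median ~ e^3 ≈ 20 t C
    amount_log_sigma: float = 1.0
    variation_range_pct: tuple[float, float] = (5.0, 20.0)
    fossil_prob: float = 0.1
    functional_units: tuple[FunctionalUnit, ...] = field(default_factory=tuple)
    period: str = "1 year"


def generate_synthetic_ledger(
    n_fluxes: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> SystemLedger:
    """Generate a valid ledger of ``n_fluxes`` random fluxes, reproducibly.

    The same (n_fluxes, seed, config) always yields the same ledger.
    """
    if n_fluxes < 0:
        raise ValueError("n_fluxes must be >= 0")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    mix = np.asarray(cfg.category_mix, dtype=float)
    mix = mix / mix.sum()

    fluxes: list[FluxRecord] = []
    for i in range(n_fluxes):
        cat = rng.choice(3, p=mix)
        if cat == 0:  # input: boundary -> system
            source = _BOUNDARY[rng.integers(len(_BOUNDARY))]
            sink = _SYSTEM[rng.integers(len(_SYSTEM))]
            sector = Sector(sink.value)
        elif cat == 1:  # output: system -> boundary
            source = _SYSTEM[rng.integers(len(_SYSTEM))]
            sink = _BOUNDARY[rng.integers(len(_BOUNDARY))]
            sector = Sector(source.value)
        else:  # internal: distinct system sites
            a, b = rng.choice(len(_SYSTEM), size=2, replace=False)
            source, sink = _SYSTEM[a], _SYSTEM[b]
            sector = Sector(source.value)

        fossil = bool(
            (source is Site.EXTERNAL or sink is Site.AIR)
            and rng.random() < cfg.fossil_prob
        )
        material = "oil" if fossil and source is Site.EXTERNAL else (
            "co2" if fossil else _MATERIALS[rng.integers(len(_MATERIALS))]
        )
        amount = float(rng.lognormal(cfg.amount_log_mean, cfg.amount_log_sigma))
        variation = float(rng.uniform(*cfg.variation_range_pct))
        fluxes.append(
            FluxRecord.make(
                id=f"syn{i:04d}",
                label=f"synthetic {source.value}->{sink.value} flux {i}",
                sector=sector,
                source=source,
                sink=sink,
                material=material,
                amount_c=amount,
                variation_pct=variation,
                fossil=fossil,
            )
        )

    return SystemLedger(
        system_name=f"synthetic ledger (seed {seed})",
        period=cfg.period,
        fluxes=fluxes,
        functional_units=list(cfg.functional_units),
        canonical_unit="t C",
    )
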