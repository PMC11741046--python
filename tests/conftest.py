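import pytest
from hypothesis import settings

from carbonledger import FluxRecord, FunctionalUnit, SystemLedger, datasets

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def flux(
    id: str,
    source: str,
    sink: str,
    amount: float,
    *,
    sector: str | None = None,
    material: str = "plant_material",
    variation: float | None = None,
    fossil: bool = False,
    label: str | None = None,
) -> FluxRecord:
    """Shorthand flux builder with the category derived from the endpoints."""
    if sector is None:
        sector = source if source in ("animal", "plant", "soil") else sink
    return FluxRecord.make(
        id=id,
        label=label or f"{source} to {sink}",
        sector=sector,
        source=source,
        sink=sink,
        material=material,
        amount_c=amount,
        variation_pct=variation,
        fossil=fossil,
    )


def ledger(*fluxes: FluxRecord, fus: list[FunctionalUnit] | None = None) -> SystemLedger:
    return SystemLedger(
        system_name="test", fluxes=list(fluxes), functional_units=fus or []
    )


@pytest.fixture(scope="session")
def coalvi():
    """The packaged consortium validation ledger (10^3 t C / year)."""
    return datasets.coalvi()
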