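"""Readers and writers: ledger CSV, DOT flowchart, structured/tabular reports.

The ledger file is a plain UTF-8 CSV with the columns ``id, label, sector,
source, sink, category, material, amount_c_t, variation_pct, fossil`` in
that order. An empty string marks a missing optional value (variation_pct).
System metadata (name, period, unit, functional units) travels in ``#``
comment lines above the header so that a ledger round-trips through one
file; a bare CSV without comments is read with default metadata.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path

from .balance import BalanceReport, Reconciliation
from .model import (
    FluxCategory,
    FluxRecord,
    FunctionalUnit,
    Sector,
    Site,
    SystemLedger,
    require_valid,
)
from .sensitivity import SensitivityResult

LEDGER_COLUMNS = [
    "id",
    "label",
    "sector",
    "source",
    "sink",
    "category",
    "material",
    "amount_c_t",
    "variation_pct",
    "fossil",
]

_TRUE = {"true", "1"}
_FALSE = {"false", "0"}


class LedgerParseError(ValueError):
    """A malformed ledger file row; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def _format_amount(x: float) -> str:
    # shortest decimal string that round-trips the float
    return repr(float(x))


def _parse_fossil(text: str, row: int) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise LedgerParseError(row, f"fossil must be one of true/false/1/0, got {text!r}")


def read_ledger(path: str | Path) -> SystemLedger:
    """Read and validate a ledger CSV; parse errors carry row numbers."""
    path = Path(path)
    meta: dict[str, str] = {}
    fus: list[FunctionalUnit] = []
    body_lines: list[str] = []
    body_start = 0
    with path.open(encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                content = line[1:].strip()
                if ":" in content:
                    key, _, value = content.partition(":")
                    key = key.strip()
                    value = value.strip()
                    if key == "functional_unit":
                        parts = [p.strip() for p in value.split("|")]
                        if len(parts) != 3:
                            raise LedgerParseError(
                                lineno, f"functional_unit needs name|quantity|units, got {value!r}"
                            )
                        try:
                            fus.append(FunctionalUnit(parts[0], float(parts[1]), parts[2]))
                        except ValueError as exc:
                            raise LedgerParseError(lineno, str(exc)) from None
                    else:
                        meta[key] = value
            else:
                if not body_lines:
                    body_start = lineno
                body_lines.append(line)

    if not body_lines:
        raise LedgerParseError(body_start or 1, "missing header row")
    reader = csv.reader(_io.StringIO("".join(body_lines)))
    header = next(reader)
    if header != LEDGER_COLUMNS:
        raise LedgerParseError(
            body_start, f"bad header: expected {LEDGER_COLUMNS}, got {header}"
        )

    fluxes: list[FluxRecord] = []
    for offset, row in enumerate(reader, start=1):
        lineno = body_start + offset
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(LEDGER_COLUMNS):
            raise LedgerParseError(
                lineno, f"expected {len(LEDGER_COLUMNS)} fields, got {len(row)}"
            )
        rec = dict(zip(LEDGER_COLUMNS, row))
        try:
            source = Site(rec["source"])
            sink = Site(rec["sink"])
            sector = Sector(rec["sector"])
            category = FluxCategory(rec["category"])
        except ValueError as exc:
            raise LedgerParseError(lineno, str(exc)) from None
        try:
            amount = float(rec["amount_c_t"])
        except ValueError:
            raise LedgerParseError(
                lineno, f"amount_c_t is not a number: {rec['amount_c_t']!r}"
            ) from None
        if amount < 0:
            raise LedgerParseError(
                lineno, f"amount_c_t must be >= 0, got {amount} (direction is source/sink)"
            )
        var_text = rec["variation_pct"].strip()
        if var_text == "":
            variation = None
        else:
            try:
                variation = float(var_text)
            except ValueError:
                raise LedgerParseError(
                    lineno, f"variation_pct is not a number: {var_text!r}"
                ) from None
        fluxes.append(
            FluxRecord(
                id=rec["id"],
                label=rec["label"],
                sector=sector,
                source=source,
                sink=sink,
                category=category,
                material=rec["material"],
                amount_c=amount,
                variation_pct=variation,
                fossil=_parse_fossil(rec["fossil"], lineno),
            )
        )

    ledger = SystemLedger(
        system_name=meta.get("system_name", path.stem),
        period=meta.get("period", "1 year"),
        fluxes=fluxes,
        functional_units=fus,
        canonical_unit=meta.get("canonical_unit", "t C"),
    )
    return require_valid(ledger)


def ledger_to_csv(ledger: SystemLedger) -> str:
    """Render a valid ledger as CSV text that :func:`read_ledger` reproduces exactly."""
    require_valid(ledger)
    buf = _io.StringIO()
    buf.write(f"# system_name: {ledger.system_name}\n")
    buf.write(f"# period: {ledger.period}\n")
    buf.write(f"# canonical_unit: {ledger.canonical_unit}\n")
    for fu in ledger.functional_units:
        buf.write(f"# functional_unit: {fu.name}|{_format_amount(fu.quantity)}|{fu.units}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(LEDGER_COLUMNS)
    for f in ledger.fluxes:
        writer.writerow(
            [
                f.id,
                f.label,
                f.sector.value,
                f.source.value,
                f.sink.value,
                f.category.value,
                f.material,
                _format_amount(f.amount_c),
                "" if f.variation_pct is None else _format_amount(f.variation_pct),
                "true" if f.fossil else "false",
            ]
        )
    return buf.getvalue()


def write_ledger(ledger: SystemLedger, path: str | Path) -> Path:
    """Write a valid ledger so that :func:`read_ledger` reproduces it exactly."""
    path = Path(path)
    path.write_text(ledger_to_csv(ledger), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# DOT flowchart

_EDGE_STYLE = {
    FluxCategory.INPUT: "solid",
    FluxCategory.OUTPUT: "dashed",
    FluxCategory.INTERNAL: "dotted",
}


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def flowchart_dot(ledger: SystemLedger) -> str:
    """Render the flux network as DOT: box nodes for sites, one edge per flux.

    Inputs are solid arrows, outputs dashed, internal transfers dotted,
    matching the conventional flowchart of the accounting scheme.
    """
    require_valid(ledger)
    lines = [
        f'digraph "{_dot_escape(ledger.system_name)}" {{',
        "  rankdir=LR;",
        '  node [shape=box];',
    ]
    sites = []
    for f in ledger.fluxes:
        for site in (f.source, f.sink):
            if site not in sites:
                sites.append(site)
    for site in sites:
        lines.append(f'  {site.value} [label="{site.value}"];')
    for f in ledger.fluxes:
        label = _dot_escape(f"{f.label}: {_format_amount(f.amount_c)} {ledger.canonical_unit}")
        lines.append(
            f'  {f.source.value} -> {f.sink.value} '
            f'[style={_EDGE_STYLE[f.category]}, label="{label}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_flowchart(ledger: SystemLedger, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(flowchart_dot(ledger), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Reports


def report_to_dict(
    report: BalanceReport,
    sens: SensitivityResult | None = None,
    recon: Reconciliation | None = None,
) -> dict:
    """Machine-readable form of a balance report (JSON-serialisable)."""
    out = {
        "system_name": report.system_name,
        "period": report.period,
        "unit": report.unit,
        "sign_convention": "inputs +, outputs -; air_change < 0 means net removal from the atmosphere",
        "total_inputs": report.total_inputs,
        "total_outputs": report.total_outputs,
        "balance": report.balance,
        "site_storage": {s.value: v for s, v in report.site_storage.items()},
        "air_change": report.air_change,
        "efficiency": report.efficiency,
        "intensity": dict(report.intensity),
        "per_fu": {
            name: table.to_dict(orient="records") for name, table in report.per_fu.items()
        },
    }
    if sens is not None:
        out["sensitivity"] = {
            "delta_in_pct": sens.delta_in_pct,
            "delta_out_pct": sens.delta_out_pct,
            "centre": sens.centre,
            "grid": [
                {"in_mult": im, "out_mult": om, "balance": b}
                for (im, om), b in sorted(sens.grid.items())
            ],
            "worst_case": sens.worst_case,
            "best_case": sens.best_case,
            "sign_robust": sens.sign_robust,
        }
    if recon is not None:
        out["reconciliation"] = {
            "conservation_residual": recon.conservation_residual,
            "decomposition_residual": recon.decomposition_residual,
            "tolerance": recon.tolerance,
            "passed": recon.passed,
        }
    return out


def _fmt_total(x: float) -> str:
    return f"{x:.1f}"


def _fmt_per_fu(x: float) -> str:
    # two decimals as in the reference layout, three for sub-0.01 magnitudes
    # that would otherwise lose their leading digit (e.g. -0.003)
    if x != 0.0 and abs(x) < 0.01:
        return f"{x:.3f}"
    return f"{x:.2f}"


_CAT_TAG = {
    FluxCategory.INPUT: "(I)",
    FluxCategory.OUTPUT: "(O)",
    FluxCategory.INTERNAL: "(N)",
}


def _flux_direction_note(f: FluxRecord, block_site: Site) -> tuple[float, str]:
    """Signed amount and direction annotation of a flux inside a sector block."""
    if f.category is FluxCategory.INPUT:
        origin = "from the air site" if f.source is Site.AIR else "from outside the system"
        return f.amount_c, origin
    if f.category is FluxCategory.OUTPUT:
        dest = "to the air site" if f.sink is Site.AIR else "to outside the system"
        return -f.amount_c, dest
    # internal: positive in the receiving block, negative in the sending one
    if f.sink is block_site:
        return f.amount_c, f"from the {f.source.value} site"
    return -f.amount_c, f"to the {f.sink.value} site"


def tabular_report(report: BalanceReport, sens: SensitivityResult | None = None) -> str:
    """Plain-text report in the reference table layout.

    Storage rows first, then one block per productive sector with
    (I)/(O)/(N)-tagged signed fluxes (internal transfers shown in both the
    sending and the receiving block), then the balance row; one extra
    column per functional unit.
    """
    ledger = report.ledger
    if ledger is None:
        raise ValueError("tabular report needs the source ledger on the report")
    fus = ledger.functional_units

    header = ["Category", f"C ({report.unit})"] + [
        f"C per {fu.units}" for fu in fus
    ]
    rows: list[list[str]] = []

    def emit(label: str, value: float) -> None:
        rows.append(
            [label, _fmt_total(value)] + [_fmt_per_fu(value / fu.quantity) for fu in fus]
        )

    rows.append(["C stored in the system sites", "", *[""] * len(fus)])
    for site in (Site.ANIMAL, Site.PLANT, Site.SOIL):
        emit(f"  {site.value.capitalize()}s" if site is not Site.SOIL else "  Soil",
             report.site_storage.get(site, 0.0))
    rows.append(["C stored outside the system", "", *[""] * len(fus)])
    emit("  Air", report.air_change)

    for sector_site in (Site.ANIMAL, Site.PLANT, Site.SOIL):
        block = [
            f
            for f in ledger.fluxes
            if f.sector.value == sector_site.value
            or (
                f.category is FluxCategory.INTERNAL
                and sector_site in (f.source, f.sink)
            )
        ]
        if not block:
            continue
        rows.append([f"C fluxes: {sector_site.value} sector", "", *[""] * len(fus)])
        for f in block:
            signed, note = _flux_direction_note(f, sector_site)
            emit(f"  {_CAT_TAG[f.category]} {f.label} ({note})", signed)

    emit("Balance (inputs-outputs)", report.balance)

    if sens is not None:
        rows.append(["Sensitivity", "", *[""] * len(fus)])
        emit(
            f"  Worst case (inputs -{sens.delta_in_pct:g}%, outputs +{sens.delta_out_pct:g}%)",
            sens.worst_case,
        )
        emit(
            f"  Best case (inputs +{sens.delta_in_pct:g}%, outputs -{sens.delta_out_pct:g}%)",
            sens.best_case,
        )
        rows.append(
            ["  Sign robust", "yes" if sens.sign_robust else "no", *[""] * len(fus)]
        )

    widths = [max(len(r[i]) for r in rows + [header]) for i in range(len(header))]
    fmt = "  ".join(f"{{:<{widths[0]}}}" if i == 0 else f"{{:>{w}}}" for i, w in enumerate(widths))
    lines = [fmt.format(*header)] + [fmt.format(*r) for r in rows]
    return "\n".join(lines) + "\n"


def write_report(
    report: BalanceReport,
    sens: SensitivityResult | None = None,
    path: str | Path = "report.json",
    format: str = "structured",
    recon: Reconciliation | None = None,
) -> Path:
    """Write a report: ``structured`` (JSON) or ``tabular`` (reference layout)."""
    path = Path(path)
    if format == "structured":
        path.write_text(
            json.dumps(report_to_dict(report, sens, recon), indent=2) + "\n",
            encoding="utf-8",
        )
    elif format == "tabular":
        path.write_text(tabular_report(report, sens), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path) -> dict:
    """Parse a structured report back into its dictionary form."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
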