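"""Report rows and rendering: the presentation layer.

All model code carries unrounded floats; rounding happens here and only for
the human-readable table format.  The mixed display precision mirrors how
published footprint tables print: footprints below 1 kgCO2e get two
significant figures, mid-range values two decimals, and large values are
shown as whole kilograms; car-km and tree-months become integers once they
exceed 10.  The ``csv`` and ``json`` formats always carry unrounded values.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import asdict, dataclass

from .errors import ValidationError
from .footprint_model import Footprint

__all__ = [
    "ReportRow",
    "row_from_footprint",
    "render_report",
    "round_half_up",
    "round_sig",
    "display_kg",
    "display_quantity",
    "display_percent",
]

FORMATS = ("table", "csv", "json")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables),
    unlike Python's banker's rounding."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures, half up."""
    if x == 0:
        return 0.0
    import math

    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round_half_up(x, ndigits)


def display_kg(x: float) -> str:
    """Format a footprint in kgCO2e at table precision."""
    if x == 0:
        return "0"
    if x < 1:
        v = round_sig(x, 2)
        return f"{v:.10f}".rstrip("0").rstrip(".")
    if x < 100:
        return f"{round_half_up(x, 2):.2f}"
    return f"{round_half_up(x, 0):,.0f}"


def display_quantity(x: float) -> str:
    """Format an equivalent (km, tree-months): integers above 10."""
    if x == 0:
        return "0"
    if x >= 10:
        return f"{round_half_up(x, 0):,.0f}"
    if x < 1:
        v = round_sig(x, 2)
        return f"{v:.10f}".rstrip("0").rstrip(".")
    return f"{round_half_up(x, 2):.2f}"


def display_percent(x: float | None) -> str:
    """Format a relative-increase column entry; the baseline shows an em dash."""
    if x is None:
        return "—"
    return f"{round_half_up(x, 0):+,.0f}%"


@dataclass(frozen=True)
class ReportRow:
    """One rendered result: a labeled footprint with its equivalents."""

    label: str
    kg_co2e: float
    tree_months: float
    tree_years: float
    car_km: float
    increase_pct: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("kg_co2e", "tree_months", "tree_years", "car_km"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def row_from_footprint(label: str, fp: Footprint, increase_pct: float | None = None) -> ReportRow:
    return ReportRow(
        label=label,
        kg_co2e=fp.kg_co2e,
        tree_months=fp.equivalents.tree_months,
        tree_years=fp.equivalents.tree_years,
        car_km=fp.equivalents.car_km,
        increase_pct=increase_pct,
        flags=fp.flags,
    )


_HEADERS = ["label", "kg_co2e", "tree_months", "tree_years", "car_km", "increase_pct", "flags"]


def render_report(rows: list[ReportRow], format: str = "table") -> str:
    """Render report rows as a fixed-width table, CSV, or JSON.

    Table output applies display rounding; csv/json carry unrounded values
    (json round-trips to the input rows exactly).
    """
    if format not in FORMATS:
        raise ValidationError(f"unknown format {format!r}; choose from {FORMATS}")
    if format == "json":
        payload = []
        for r in rows:
            d = asdict(r)
            d["flags"] = list(r.flags)
            payload.append(d)
        return json.dumps(payload, indent=2)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(_HEADERS)
        for r in rows:
            writer.writerow(
                [r.label, repr(r.kg_co2e), repr(r.tree_months), repr(r.tree_years),
                 repr(r.car_km), "" if r.increase_pct is None else repr(r.increase_pct),
                 ";".join(r.flags)]
            )
        return buf.getvalue()
    # fixed-width table
    header = ["task", "kgCO2e", "tree-months", "tree-years", "km (EU car)", "increase", "flags"]
    cells = [header]
    for r in rows:
        cells.append(
            [
                r.label,
                display_kg(r.kg_co2e),
                display_quantity(r.tree_months),
                display_quantity(r.tree_years),
                display_quantity(r.car_km),
                display_percent(r.increase_pct) if r.increase_pct is not None else "—",
                ",".join(r.flags) or "-",
            ]
        )
    widths = [max(len(row[i]) for row in cells) for i in range(len(header))]
    lines = []
    for j, row in enumerate(cells):
        lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip())
        if j == 0:
            lines.append("  ".join("-" * w for w in widths))
    return "\n".join(lines) + "\n"
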