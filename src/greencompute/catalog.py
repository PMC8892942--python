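"""Benchmark catalog: published per-tool footprints as data.

The shipped catalog (``data/benchmark_catalog.csv``) transcribes a published
survey of 44 tool-experiment benchmarks across genome assembly,
metagenomics, phylogenetics, RNA-seq, GWAS/eQTL mapping, and molecular
simulation/docking.  Each row records the runtime and memory the benchmark
reported, the footprint printed for it, contextual equivalents, and an
optional scaling note.

Most rows cannot be recomputed from the catalog alone because the processor
hardware was only reported in supplementary material; those carry
``hardware_provenance=supplementary`` with empty hardware fields (users may
fill them in to unlock reproduction).  Rows whose inputs are complete are
recomputed with the footprint model and compared against the printed value.

The file format is CSV with quoted free-text fields, preceded by a
schema-version line (``# greencompute-catalog v1``).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .errors import ValidationError
from .footprint_model import (
    CORE_HOURS,
    WALL_CLOCK,
    FacilityContext,
    MemoryAllocation,
    ProcessorAllocation,
    TaskResources,
    compute_footprint,
)
from .reference_data import parse_duration
from .scaling import ScalingModel, parse_scaling, percent_change

__all__ = [
    "CatalogEntry",
    "ReproductionRecord",
    "IncreaseRecord",
    "load_catalog",
    "write_catalog",
    "reproduce_entry",
    "rebuild_increase_columns",
]

SCHEMA_LINE = "# greencompute-catalog v1"

COLUMNS = [
    "task_group",
    "tool",
    "version",
    "experiment",
    "runtime",
    "runtime_kind",
    "memory_gb",
    "cores",
    "power_per_core",
    "pue",
    "ci",
    "printed_kg",
    "printed_tree_months",
    "printed_km",
    "printed_increase_pct",
    "scaling",
    "hardware_provenance",
    "usage_factor",
]

PROVENANCES = ("main-text", "supplementary", "absent")

Range = tuple[float, float]


def _parse_range(text: str, field: str) -> Range:
    """Parse "x" or "lo-hi" into a (lo, hi) pair (lo == hi for scalars)."""
    try:
        v = float(text)
        return (v, v)
    except ValueError:
        pass
    # split on "-" unless it is part of an exponent like 1e-05
    parts = re.split(r"(?<![eE])-", text)
    try:
        if len(parts) == 2:
            lo, hi = float(parts[0]), float(parts[1])
            if lo > hi:
                raise ValueError
            return (lo, hi)
        raise ValueError
    except ValueError:
        raise ValidationError(f"cannot parse {field} value {text!r}") from None


def _format_range(r: Range) -> str:
    if r[0] == r[1]:
        return f"{r[0]:.17g}"
    return f"{r[0]:.17g}-{r[1]:.17g}"


def _parse_runtime(text: str) -> Range:
    """Runtime text, either scalar or a " to "-separated range, in hours."""
    if " to " in text:
        lo, hi = text.split(" to ", 1)
        return (parse_duration(lo), parse_duration(hi))
    h = parse_duration(text)
    return (h, h)


@dataclass(frozen=True)
class CatalogEntry:
    """One benchmark row: a tool run on one experiment, with its printed
    footprint and the resources it consumed.

    Quantities that the source printed as ranges (footprint, memory,
    runtime) are stored as (lo, hi) pairs with lo == hi for scalars;
    ``is_range`` is True when any of them is a genuine range.  ``memory_gb``
    is None when the benchmark did not report memory (the footprint then
    excludes the memory term).
    """

    task_group: str
    tool: str
    version: str
    experiment: str
    runtime: str  # original text, e.g. "60 h 58 min"
    runtime_kind: str
    hours: Range  # parsed decimal hours
    memory_gb: Range | None
    cores: int | None
    power_per_core: float | None
    pue: float
    ci: float
    printed_kg: Range
    printed_tree_months: Range
    printed_km: Range
    printed_increase_pct: float | None
    scaling: ScalingModel | None
    hardware_provenance: str
    usage_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.runtime_kind not in (WALL_CLOCK, CORE_HOURS):
            raise ValidationError(f"bad runtime_kind {self.runtime_kind!r}")
        if not self.hours[0] > 0:
            raise ValidationError(f"parsed runtime must be > 0 h, got {self.hours}")
        if self.printed_kg[0] < 0:
            raise ValidationError(f"printed_kg must be >= 0, got {self.printed_kg}")
        if self.memory_gb is not None and self.memory_gb[0] < 0:
            raise ValidationError(f"memory_gb must be >= 0, got {self.memory_gb}")
        if self.hardware_provenance not in PROVENANCES:
            raise ValidationError(f"bad hardware_provenance {self.hardware_provenance!r}")
        if self.hardware_provenance == "main-text" and (
            self.cores is None or self.power_per_core is None
        ):
            raise ValidationError(
                f"{self.tool}: main-text hardware provenance requires cores and power_per_core"
            )

    @property
    def is_range(self) -> bool:
        ranged = [self.hours, self.printed_kg, self.printed_tree_months, self.printed_km]
        if self.memory_gb is not None:
            ranged.append(self.memory_gb)
        return any(lo != hi for lo, hi in ranged)

    @property
    def printed_kg_value(self) -> float | None:
        """Scalar printed footprint, or None for range rows."""
        lo, hi = self.printed_kg
        return lo if lo == hi else None

    @property
    def reproducible(self) -> bool:
        """True when the row carries everything the model needs."""
        return (
            self.cores is not None
            and self.power_per_core is not None
            and not self.is_range
        )

    def resources(self) -> TaskResources:
        """Build the model inputs from this row (reproducible rows only)."""
        if not self.reproducible:
            raise ValidationError(f"{self.tool}: row is not reproducible")
        if self.memory_gb is None:
            memory = MemoryAllocation.unknown()
        else:
            memory = MemoryAllocation(size_gb=self.memory_gb[0])
        return TaskResources(
            duration=self.hours[0],
            processors=(
                ProcessorAllocation(self.cores, self.power_per_core, self.usage_factor),
            ),
            memory=memory,
            duration_kind=self.runtime_kind,
        )

    def facility(self) -> FacilityContext:
        return FacilityContext(pue=self.pue, ci=self.ci)


@dataclass(frozen=True)
class ReproductionRecord:
    """Printed-vs-recomputed comparison for one row (a report, not an
    assertion: non-reproducible rows get ``reproducible=False``)."""

    task_group: str
    tool: str
    experiment: str
    printed_kg: float | None
    computed_kg: float | None
    deviation: float | None  # (computed - printed) / printed
    reproducible: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class IncreaseRecord:
    """Rebuilt relative-increase column for one row within its task group."""

    task_group: str
    tool: str
    experiment: str
    is_baseline: bool
    rebuilt_pct: float | None  # None for the baseline row
    printed_pct: float | None
    consistent: bool | None  # None when not comparable


def _row_to_entry(row: dict[str, str]) -> CatalogEntry:
    memory_text = row["memory_gb"].strip()
    scaling_text = row["scaling"].strip()
    cores_text = row["cores"].strip()
    power_text = row["power_per_core"].strip()
    inc_text = row["printed_increase_pct"].strip()
    usage_text = row.get("usage_factor", "").strip()
    return CatalogEntry(
        task_group=row["task_group"].strip(),
        tool=row["tool"].strip(),
        version=row["version"].strip(),
        experiment=row["experiment"].strip(),
        runtime=row["runtime"].strip(),
        runtime_kind=row["runtime_kind"].strip(),
        hours=_parse_runtime(row["runtime"].strip()),
        memory_gb=_parse_range(memory_text, "memory_gb") if memory_text else None,
        cores=int(cores_text) if cores_text else None,
        power_per_core=float(power_text) if power_text else None,
        pue=float(row["pue"]),
        ci=float(row["ci"]),
        printed_kg=_parse_range(row["printed_kg"], "printed_kg"),
        printed_tree_months=_parse_range(row["printed_tree_months"], "printed_tree_months"),
        printed_km=_parse_range(row["printed_km"], "printed_km"),
        printed_increase_pct=float(inc_text) if inc_text else None,
        scaling=parse_scaling(scaling_text) if scaling_text else None,
        hardware_provenance=row["hardware_provenance"].strip(),
        usage_factor=float(usage_text) if usage_text else 1.0,
    )


def load_catalog(path: str | Path | None = None) -> list[CatalogEntry]:
    """Load and validate a catalog file; default: the bundled transcription.

    Raises a row-addressed :class:`ValidationError` on schema mismatch,
    unparseable runtimes, or negative quantities, and ``"no rows"`` on an
    empty file.
    """
    if path is None:
        text = resources.files("greencompute").joinpath("data/benchmark_catalog.csv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# greencompute-catalog"):
        raise ValidationError(
            f"missing schema line; expected first line starting with {SCHEMA_LINE!r}"
        )
    reader = csv.DictReader(io.StringIO("\n".join(lines[1:])))
    if reader.fieldnames is None:
        raise ValidationError("no rows: catalog has no header")
    missing = [c for c in COLUMNS if c not in reader.fieldnames and c != "usage_factor"]
    if missing:
        raise ValidationError(f"catalog header missing columns: {missing}")
    entries: list[CatalogEntry] = []
    errors: list[str] = []
    for i, row in enumerate(reader, start=1):
        try:
            entries.append(_row_to_entry(row))
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i} ({row.get('tool', '?')}): {exc}")
    if errors:
        raise ValidationError("catalog validation failed:\n" + "\n".join(errors))
    if not entries:
        raise ValidationError("no rows in catalog")
    return entries


def write_catalog(entries: Sequence[CatalogEntry], path: str | Path) -> None:
    """Write entries back to the schema-versioned CSV format."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(SCHEMA_LINE + "\n")
        writer = csv.DictWriter(fh, fieldnames=COLUMNS)
        writer.writeheader()
        for e in entries:
            writer.writerow(
                {
                    "task_group": e.task_group,
                    "tool": e.tool,
                    "version": e.version,
                    "experiment": e.experiment,
                    "runtime": e.runtime,
                    "runtime_kind": e.runtime_kind,
                    "memory_gb": _format_range(e.memory_gb) if e.memory_gb is not None else "",
                    "cores": str(e.cores) if e.cores is not None else "",
                    "power_per_core": f"{e.power_per_core:.17g}" if e.power_per_core is not None else "",
                    "pue": f"{e.pue:.17g}",
                    "ci": f"{e.ci:.17g}",
                    "printed_kg": _format_range(e.printed_kg),
                    "printed_tree_months": _format_range(e.printed_tree_months),
                    "printed_km": _format_range(e.printed_km),
                    "printed_increase_pct": f"{e.printed_increase_pct:.17g}" if e.printed_increase_pct is not None else "",
                    "scaling": e.scaling.to_token() if e.scaling is not None else "",
                    "hardware_provenance": e.hardware_provenance,
                    "usage_factor": f"{e.usage_factor:.17g}",
                }
            )


def reproduce_entry(entry: CatalogEntry) -> ReproductionRecord:
    """Recompute a row's footprint from its resources and compare to the
    printed value.  Rows without complete hardware return
    ``reproducible=False`` and never raise."""
    if not entry.reproducible:
        return ReproductionRecord(
            task_group=entry.task_group,
            tool=entry.tool,
            experiment=entry.experiment,
            printed_kg=entry.printed_kg_value,
            computed_kg=None,
            deviation=None,
            reproducible=False,
        )
    fp = compute_footprint(entry.resources(), entry.facility())
    printed = entry.printed_kg_value
    deviation = (fp.kg_co2e - printed) / printed if printed else None
    return ReproductionRecord(
        task_group=entry.task_group,
        tool=entry.tool,
        experiment=entry.experiment,
        printed_kg=printed,
        computed_kg=fp.kg_co2e,
        deviation=deviation,
        reproducible=True,
        flags=fp.flags,
    )


def rebuild_increase_columns(
    entries: Sequence[CatalogEntry],
    tolerance_points: float = 2.0,
    tolerance_relative: float = 0.02,
) -> list[IncreaseRecord]:
    """Rebuild the per-group relative-increase column from printed footprints.

    Rows are grouped by (task group, experiment); within each group the
    lowest-footprint tool is the baseline and every other row gets
    ``percent_change`` against it.  Range rows are excluded.  Rebuilt values
    are compared with the printed column where present: the printed values
    were derived from unrounded footprints, so rebuilding from rounded ones
    can disagree — mismatches beyond the tolerance are flagged
    (``consistent=False``), never silently dropped.
    """
    groups: dict[tuple[str, str], list[CatalogEntry]] = {}
    for e in entries:
        if e.printed_kg_value is None:  # ranged footprints are excluded
            continue
        groups.setdefault((e.task_group, e.experiment), []).append(e)
    records: list[IncreaseRecord] = []
    for key, group in groups.items():
        kgs = [e.printed_kg_value for e in group]
        if all(kg == 0 for kg in kgs):
            raise ValidationError(f"group {key} has only zero-footprint rows")
        baseline = min(group, key=lambda e: e.printed_kg_value)
        for e in group:
            if e is baseline:
                records.append(
                    IncreaseRecord(e.task_group, e.tool, e.experiment, True, None, e.printed_increase_pct, None)
                )
                continue
            rebuilt = percent_change(baseline.printed_kg_value, e.printed_kg_value)
            printed = e.printed_increase_pct
            if printed is None:
                consistent = None
            else:
                diff = abs(rebuilt - printed)
                rel = diff / abs(printed) if printed else float("inf")
                consistent = diff <= tolerance_points or rel <= tolerance_relative
            records.append(
                IncreaseRecord(e.task_group, e.tool, e.experiment, False, rebuilt, printed, consistent)
            )
    return records
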