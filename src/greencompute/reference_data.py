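"""Reference constants and lookup tables for the footprint model.

Everything the model treats as a physical or empirical constant lives here:
the memory power density (W/GB), the Wh->kWh factor, contextual-equivalent
conversion factors (car km, tree-months), regional carbon intensities
(kgCO2e/kWh), facility power-usage-effectiveness (PUE) values, and a small
processor power-draw catalog.  The values are loaded from a bundled,
human-editable YAML file (``data/reference_data.yaml``); an override file
with the same schema can be supplied by the user.

Also provides :func:`parse_duration` for the human-readable runtime strings
used in benchmark catalogs ("60 h 58 min", "3 min 21 s").
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import yaml

from .errors import DurationParseError, LookupKeyError, ValidationError

__all__ = [
    "Constants",
    "ProcessorInfo",
    "ReferenceData",
    "default_reference_data",
    "get_carbon_intensity",
    "get_pue",
    "get_processor",
    "parse_duration",
    "format_duration",
]


@dataclass(frozen=True)
class Constants:
    """Scalar constants of the energy/carbon model.

    Attributes
    ----------
    memory_power_per_gb : float
        Power drawn per GB of allocated memory (``Pm``), W/GB.
    kwh_per_wh : float
        Conversion factor Wh -> kWh (0.001).
    car_emission_kg_per_km : float
        Emissions of an average European car, kgCO2e/km.
    tree_month_kg : float
        CO2e sequestered by a mature tree in one month, kgCO2e.
    tree_month_kg_unrounded : float
        Unrounded candidate (11/12) for the same constant; some published
        tree-month equivalents only reproduce with this value.  Documented,
        not used by default.
    tree_months_per_year : int
        Exactly 12.
    default_core_power : float
        Default per-core CPU power draw, W.
    default_usage_factor : float
        Default core usage factor in [0, 1].
    """

    memory_power_per_gb: float = 0.3725
    kwh_per_wh: float = 0.001
    car_emission_kg_per_km: float = 0.175
    tree_month_kg: float = 0.917
    tree_month_kg_unrounded: float = 11.0 / 12.0
    tree_months_per_year: int = 12
    default_core_power: float = 12.0
    default_usage_factor: float = 1.0


@dataclass(frozen=True)
class ProcessorInfo:
    """One processor in the power-draw catalog."""

    name: str
    kind: str  # "cpu" | "gpu"
    core_count: int
    total_power: float  # W, whole package
    provenance: str  # "primary" | "vendor"

    def __post_init__(self) -> None:
        if self.kind not in ("cpu", "gpu"):
            raise ValidationError(f"processor kind must be cpu or gpu, got {self.kind!r}")
        if self.core_count < 1:
            raise ValidationError("core_count must be >= 1")
        if not self.total_power > 0:
            raise ValidationError("total_power must be > 0")
        if self.provenance not in ("primary", "vendor"):
            raise ValidationError(f"provenance must be primary or vendor, got {self.provenance!r}")

    @property
    def power_per_core(self) -> float:
        """Per-core power draw in W (``Pc``)."""
        return self.total_power / self.core_count


def _canonical(key: str) -> str:
    return key.strip().lower().replace(" ", "-").replace("_", "-")


class ReferenceData:
    """Immutable registry of constants, CI and PUE tables, and processors.

    Lookups are case-insensitive on a documented key set; unknown keys raise
    :class:`~greencompute.errors.LookupKeyError` naming the valid keys.
    """

    DEFAULT_FACILITY = "global-average"
    DEFAULT_REGION = "global"

    def __init__(
        self,
        constants: Constants,
        carbon_intensity: Mapping[str, float],
        ci_aliases: Mapping[str, str],
        pue: Mapping[str, float],
        pue_aliases: Mapping[str, str],
        processors: tuple[ProcessorInfo, ...],
        schema_version: int = 1,
    ):
        for region, ci in carbon_intensity.items():
            if not ci > 0:
                raise ValidationError(f"carbon intensity for {region!r} must be > 0, got {ci}")
        for fac, p in pue.items():
            if not p >= 1:
                raise ValidationError(f"PUE for {fac!r} must be >= 1, got {p}")
        self.constants = constants
        self.schema_version = schema_version
        self._ci = MappingProxyType({_canonical(k): float(v) for k, v in carbon_intensity.items()})
        self._ci_aliases = MappingProxyType({_canonical(k): _canonical(v) for k, v in ci_aliases.items()})
        self._pue = MappingProxyType({_canonical(k): float(v) for k, v in pue.items()})
        self._pue_aliases = MappingProxyType({_canonical(k): _canonical(v) for k, v in pue_aliases.items()})
        self._processors = MappingProxyType({p.name: p for p in processors})

    # -- construction -----------------------------------------------------

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ReferenceData":
        consts = data.get("constants", {})
        known = {f for f in Constants.__dataclass_fields__}
        constants = Constants(**{k: v for k, v in consts.items() if k in known})
        processors = tuple(
            ProcessorInfo(
                name=_canonical(p["name"]),
                kind=p["kind"],
                core_count=int(p["core_count"]),
                total_power=float(p["total_power"]),
                provenance=p["provenance"],
            )
            for p in data.get("processors", [])
        )
        return cls(
            constants=constants,
            carbon_intensity=data.get("carbon_intensity", {}),
            ci_aliases=data.get("carbon_intensity_aliases", {}),
            pue=data.get("pue", {}),
            pue_aliases=data.get("pue_aliases", {}),
            processors=processors,
            schema_version=int(data.get("schema_version", 1)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ReferenceData":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"reference data file {path} is not a mapping")
        return cls.from_mapping(data)

    @classmethod
    def bundled(cls) -> "ReferenceData":
        text = resources.files("greencompute").joinpath("data/reference_data.yaml").read_text("utf-8")
        return cls.from_mapping(yaml.safe_load(text))

    # -- lookups ----------------------------------------------------------

    @property
    def regions(self) -> list[str]:
        return sorted(self._ci)

    @property
    def facilities(self) -> list[str]:
        return sorted(self._pue)

    @property
    def processors(self) -> list[ProcessorInfo]:
        return list(self._processors.values())

    def _resolve(self, key: str, table: Mapping[str, float], aliases: Mapping[str, str], kind: str) -> str:
        k = _canonical(key)
        k = aliases.get(k, k)
        if k not in table:
            raise LookupKeyError(kind, key, list(table))
        return k

    def get_carbon_intensity(self, region: str | None = None) -> float:
        """Carbon intensity (kgCO2e/kWh) for a region; default: global average."""
        region = region or self.DEFAULT_REGION
        return self._ci[self._resolve(region, self._ci, self._ci_aliases, "region")]

    def get_pue(self, facility: str | None = None) -> float:
        """PUE for a facility; default: the global-average data center."""
        facility = facility or self.DEFAULT_FACILITY
        return self._pue[self._resolve(facility, self._pue, self._pue_aliases, "facility")]

    def get_processor(self, name: str) -> ProcessorInfo:
        k = _canonical(name)
        if k not in self._processors:
            raise LookupKeyError("processor", name, list(self._processors))
        return self._processors[k]


@lru_cache(maxsize=1)
def default_reference_data() -> ReferenceData:
    """The registry loaded from the bundled YAML file (cached)."""
    return ReferenceData.bundled()


def get_carbon_intensity(region: str | None = None) -> float:
    return default_reference_data().get_carbon_intensity(region)


def get_pue(facility: str | None = None) -> float:
    return default_reference_data().get_pue(facility)


def get_processor(name: str) -> ProcessorInfo:
    return default_reference_data().get_processor(name)


# -- duration parsing -----------------------------------------------------

_NUMBER = r"(?:\d[\d,]*(?:\.\d+)?|\.\d+)(?:[eE][+-]?\d+)?"
_TOKEN_RE = re.compile(
    rf"(?P<num>{_NUMBER})\s*(?P<unit>hours?|hrs?|h|minutes?|mins?|min|m|seconds?|secs?|sec|s)(?![a-z])",
    re.IGNORECASE,
)
_UNIT_HOURS = {"h": 1.0, "hr": 1.0, "hrs": 1.0, "hour": 1.0, "hours": 1.0,
               "m": 1 / 60, "min": 1 / 60, "mins": 1 / 60, "minute": 1 / 60, "minutes": 1 / 60,
               "s": 1 / 3600, "sec": 1 / 3600, "secs": 1 / 3600, "second": 1 / 3600, "seconds": 1 / 3600}
_UNIT_ORDER = {1.0: 0, 1 / 60: 1, 1 / 3600: 2}


def parse_duration(text: str) -> float:
    """Parse a human-readable duration into decimal hours.

    Accepts any combination of hour, minute, and second components in
    descending order, e.g. ``"60 h 58 min"``, ``"3 min 21 s"``, ``"0.11 s"``,
    ``"300,000 h"``.  At least one component is required.

    Returns
    -------
    float
        Duration in decimal hours: ``h + min/60 + s/3600``.

    Raises
    ------
    DurationParseError
        If the text is empty, contains unrecognized tokens, repeats a unit,
        or lists units out of order.
    """
    if not isinstance(text, str) or not text.strip():
        raise DurationParseError(f"empty duration string: {text!r}")
    pos = 0
    total = 0.0
    seen: list[int] = []
    s = text.strip()
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise DurationParseError(f"cannot parse duration {text!r} at {s[pos:]!r}")
        factor = _UNIT_HOURS[m.group("unit").lower()]
        order = _UNIT_ORDER[factor]
        if seen and order <= seen[-1]:
            raise DurationParseError(
                f"duration components out of order or repeated in {text!r}"
            )
        seen.append(order)
        value = float(m.group("num").replace(",", ""))
        total += value * factor
        pos = m.end()
        while pos < len(s) and s[pos] in " \t":
            pos += 1
    return total


def format_duration(hours: float) -> str:
    """Render decimal hours as an ``"H h M min S s"`` string.

    Inverse of :func:`parse_duration` up to floating-point rounding; seconds
    keep full precision so the round trip is exact to ~1e-9 hours.
    """
    if hours < 0:
        raise ValidationError(f"negative duration: {hours}")
    h = int(hours)
    rem_min = (hours - h) * 60.0
    m = int(rem_min)
    sec = (rem_min - m) * 60.0
    parts = []
    if h:
        parts.append(f"{h} h")
    if m:
        parts.append(f"{m} min")
    if sec or not parts:
        parts.append(f"{sec:.9g} s")
    return " ".join(parts)
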