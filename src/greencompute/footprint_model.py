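"""The core energy and carbon model for computational jobs.

A job's energy use is modeled from its running time, the processing cores it
uses, the memory it has allocated, and the efficiency of the facility:

    E [kWh] = t * (sum_i nc_i * Pc_i * uc_i  +  nm * Pm) * PUE * 0.001

where ``t`` is the running time in hours, ``nc`` the number of cores each
drawing ``Pc`` W at usage factor ``uc``, ``nm`` the allocated memory in GB
drawing ``Pm`` W/GB, and PUE the facility's power usage effectiveness.  The
carbon footprint is then

    C [kgCO2e] = E * CI

with CI the carbon intensity of the local electricity grid in kgCO2e/kWh.

Memory is charged once per job regardless of core count, and its power
draw depends on the memory *allocated*, not the memory actually touched.
Several processor allocations (e.g. CPU + GPU) sum inside the parenthesis.
Aggregated benchmarks reported in total core-hours are modeled as a single
core (``nc=1``) running for the stated core-hours, with memory charged over
that full duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError
from .reference_data import Constants, ReferenceData, default_reference_data

__all__ = [
    "ProcessorAllocation",
    "MemoryAllocation",
    "TaskResources",
    "FacilityContext",
    "EnergyBreakdown",
    "Equivalents",
    "Footprint",
    "compute_energy",
    "compute_footprint",
    "memory_energy_fraction",
    "contextualize",
]

WALL_CLOCK = "wall-clock"
CORE_HOURS = "core-hours"
MEMORY_EXCLUDED = "memory_excluded"


@dataclass(frozen=True)
class ProcessorAllocation:
    """A homogeneous block of processing cores assigned to a job.

    ``n_cores`` cores each drawing ``power_per_core`` W, used at usage
    factor ``usage_factor`` (1 = fully busy). GPUs are modeled identically
    with the whole device as one "core"; the usage factor is applied
    uniformly to CPUs and GPUs.
    """

    n_cores: int
    power_per_core: float
    usage_factor: float = 1.0
    label: str = "cpu"

    def __post_init__(self) -> None:
        if not isinstance(self.n_cores, int) or self.n_cores < 1:
            raise ValidationError(f"n_cores must be a positive integer, got {self.n_cores!r}")
        if not (math.isfinite(self.power_per_core) and self.power_per_core > 0):
            raise ValidationError(f"power_per_core must be > 0 W, got {self.power_per_core!r}")
        if not (0.0 <= self.usage_factor <= 1.0):
            raise ValidationError(f"usage_factor must be in [0, 1], got {self.usage_factor!r}")

    @property
    def power_draw(self) -> float:
        """Effective power draw of this allocation: nc * Pc * uc, in W."""
        return self.n_cores * self.power_per_core * self.usage_factor


@dataclass(frozen=True)
class MemoryAllocation:
    """Memory reserved for a job: ``size_gb`` GB drawing ``power_per_gb`` W/GB.

    ``known=False`` marks jobs whose memory allocation was not reported; the
    memory term is then zero and downstream results carry a
    ``memory_excluded`` flag instead of silently pretending 0 GB was real.
    """

    size_gb: float = 0.0
    power_per_gb: float = Constants.memory_power_per_gb
    known: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.size_gb) and self.size_gb >= 0):
            raise ValidationError(f"memory size_gb must be >= 0, got {self.size_gb!r}")
        if not self.power_per_gb > 0:
            raise ValidationError(f"power_per_gb must be > 0, got {self.power_per_gb!r}")

    @classmethod
    def unknown(cls) -> "MemoryAllocation":
        return cls(size_gb=0.0, known=False)

    @property
    def power_draw(self) -> float:
        """nm * Pm in W; zero when the allocation is unknown."""
        return self.size_gb * self.power_per_gb if self.known else 0.0


@dataclass(frozen=True)
class TaskResources:
    """What a job consumed: duration, processor allocations, memory.

    ``duration_kind`` distinguishes wall-clock hours from aggregated
    core-hours; core-hour totals must be described as a single pseudo-core
    (``nc=1``) so the product nc*t is not double counted.
    """

    duration: float
    processors: tuple[ProcessorAllocation, ...]
    memory: MemoryAllocation = field(default_factory=MemoryAllocation)
    duration_kind: str = WALL_CLOCK

    def __post_init__(self) -> None:
        if not (math.isfinite(self.duration) and self.duration >= 0):
            raise ValidationError(f"duration must be >= 0 hours, got {self.duration!r}")
        if isinstance(self.processors, ProcessorAllocation):
            object.__setattr__(self, "processors", (self.processors,))
        else:
            object.__setattr__(self, "processors", tuple(self.processors))
        if not self.processors:
            raise ValidationError("at least one ProcessorAllocation is required")
        if self.duration_kind not in (WALL_CLOCK, CORE_HOURS):
            raise ValidationError(f"duration_kind must be {WALL_CLOCK!r} or {CORE_HOURS!r}")
        if self.duration_kind == CORE_HOURS:
            if len(self.processors) != 1 or self.processors[0].n_cores != 1:
                raise ValidationError(
                    "core-hours durations require exactly one allocation with n_cores=1"
                )

    @property
    def processor_power(self) -> float:
        """Total effective processor power draw, sum of nc*Pc*uc, in W."""
        return sum(p.power_draw for p in self.processors)


@dataclass(frozen=True)
class FacilityContext:
    """Where a job ran: the facility's PUE and the grid's carbon intensity."""

    pue: float = 1.67
    ci: float = 0.475
    region: str = "global"
    facility: str = "global-average"

    def __post_init__(self) -> None:
        if not self.pue >= 1:
            raise ValidationError(f"PUE must be >= 1, got {self.pue!r}")
        if not self.ci >= 0:
            raise ValidationError(f"carbon intensity must be >= 0, got {self.ci!r}")

    @classmethod
    def from_labels(
        cls,
        region: str | None = None,
        facility: str | None = None,
        reference: ReferenceData | None = None,
    ) -> "FacilityContext":
        """Build a context from reference-table keys (case-insensitive)."""
        ref = reference or default_reference_data()
        return cls(
            pue=ref.get_pue(facility),
            ci=ref.get_carbon_intensity(region),
            region=region or ref.DEFAULT_REGION,
            facility=facility or ref.DEFAULT_FACILITY,
        )


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy split into compute and memory shares, in kWh.

    ``memory_fraction`` is the share f = memory/total of the job's energy
    attributable to allocated memory (0 when total is zero).
    """

    compute_kwh: float
    memory_kwh: float

    @property
    def total_kwh(self) -> float:
        return self.compute_kwh + self.memory_kwh

    @property
    def memory_fraction(self) -> float:
        total = self.total_kwh
        return self.memory_kwh / total if total > 0 else 0.0


@dataclass(frozen=True)
class Equivalents:
    """Contextual equivalents of a footprint: intuitive, everyday units."""

    tree_months: float
    tree_years: float
    car_km: float


@dataclass(frozen=True)
class Footprint:
    """A job's carbon footprint in kgCO2e, with its energy breakdown and
    contextual equivalents.  ``flags`` carries caveats such as
    ``memory_excluded`` for jobs whose memory allocation was unreported."""

    kg_co2e: float
    energy: EnergyBreakdown
    equivalents: Equivalents
    flags: tuple[str, ...] = ()


def compute_energy(resources: TaskResources, facility: FacilityContext) -> EnergyBreakdown:
    """Energy needed by a job, split into compute and memory shares (kWh).

    compute = t * sum(nc*Pc*uc) * PUE * 0.001 and
    memory  = t * nm*Pm * PUE * 0.001; the 0.001 converts Wh to kWh.
    """
    scale = resources.duration * facility.pue * Constants.kwh_per_wh
    return EnergyBreakdown(
        compute_kwh=scale * resources.processor_power,
        memory_kwh=scale * resources.memory.power_draw,
    )


def compute_footprint(
    resources: TaskResources,
    facility: FacilityContext,
    constants: Constants = Constants(),
) -> Footprint:
    """Carbon footprint C = E * CI of a job, in kgCO2e, with equivalents."""
    energy = compute_energy(resources, facility)
    kg = energy.total_kwh * facility.ci
    flags = () if resources.memory.known else (MEMORY_EXCLUDED,)
    return Footprint(
        kg_co2e=kg,
        energy=energy,
        equivalents=contextualize(kg, constants),
        flags=flags,
    )


def memory_energy_fraction(resources: TaskResources) -> float:
    """Share f of a job's energy going to memory: nm*Pm / (sum nc*Pc*uc + nm*Pm).

    Independent of duration, PUE, and carbon intensity, since those scale
    both terms identically.
    """
    proc = resources.processor_power
    mem = resources.memory.power_draw
    total = proc + mem
    if total <= 0:
        raise ValidationError("memory fraction undefined: all power terms are zero")
    return mem / total


def contextualize(kg_co2e: float, constants: Constants = Constants()) -> Equivalents:
    """Convert kgCO2e into car-km and tree sequestration equivalents.

    car_km = C / 0.175 (average EU car); tree_months = C / 0.917 (monthly
    sequestration of a mature tree); tree_years = tree_months / 12.
    Values are carried unrounded; display rounding is the reporting layer's
    job.
    """
    if not kg_co2e >= 0:
        raise ValidationError(f"kg_co2e must be >= 0, got {kg_co2e!r}")
    tree_months = kg_co2e / constants.tree_month_kg
    return Equivalents(
        tree_months=tree_months,
        tree_years=tree_months / constants.tree_months_per_year,
        car_km=kg_co2e / constants.car_emission_kg_per_km,
    )
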