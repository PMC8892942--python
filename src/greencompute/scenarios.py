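"""Decision analyses built on the footprint model.

Four questions a researcher can act on:

* how much does over-allocating memory inflate a job's footprint;
* what does parallelizing across more cores buy in runtime and cost in
  carbon;
* how much faster must a GPU run than a CPU before it is the greener
  choice;
* how much does moving the same job to a different facility or country
  change its footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .footprint_model import (
    FacilityContext,
    MemoryAllocation,
    ProcessorAllocation,
    TaskResources,
    compute_footprint,
)
from .scaling import percent_change

__all__ = [
    "OverallocationPoint",
    "ParallelObservation",
    "ParallelConfigReport",
    "LocationOption",
    "LocationReport",
    "memory_overallocation_curve",
    "parallelization_tradeoff",
    "gpu_cpu_breakeven",
    "compare_locations",
    "reduction_between",
]


@dataclass(frozen=True)
class OverallocationPoint:
    """Footprint increase at one over-allocation level.

    ``overallocation`` x counts *extra* multiples of the required memory:
    allocated = (1 + x) * required, so x=5 is a 5-fold over-allocation on
    top of what the job needs.
    """

    overallocation: float
    increase_pct: float


@dataclass(frozen=True)
class ParallelObservation:
    """Measured runtime of one core-count configuration."""

    n_cores: int
    runtime: float  # hours

    def __post_init__(self) -> None:
        if not (isinstance(self.n_cores, int) and self.n_cores >= 1):
            raise ValidationError(f"n_cores must be a positive integer, got {self.n_cores!r}")
        if not self.runtime > 0:
            raise ValidationError(f"runtime must be > 0 h, got {self.runtime!r}")


@dataclass(frozen=True)
class ParallelConfigReport:
    """Footprint and speedup of one configuration, relative to the baseline."""

    n_cores: int
    runtime: float
    kg_co2e: float
    speedup: float
    footprint_change_pct: float


@dataclass(frozen=True)
class LocationOption:
    """A candidate facility/region to run a job in."""

    label: str
    facility: FacilityContext


@dataclass(frozen=True)
class LocationReport:
    """Footprint of the same underlying job at one location."""

    label: str
    facility: FacilityContext
    kg_co2e: float
    change_pct: float  # vs the baseline facility


def memory_overallocation_curve(
    f: float, xs: Iterable[float]
) -> list[OverallocationPoint]:
    """Footprint increase from reserving (1+x) times the required memory.

    With baseline memory energy fraction f, allocating (1+x)*nm GB scales
    the memory power term by (1+x) and leaves the compute term alone, so
    the footprint grows by exactly 100 * f * x percent.  PUE, CI, and
    duration cancel.
    """
    if not (0.0 <= f < 1.0):
        raise ValidationError(f"memory energy fraction must be in [0, 1), got {f!r}")
    points = []
    for x in xs:
        if x < 0:
            raise ValidationError(f"over-allocation factor must be >= 0, got {x!r}")
        points.append(OverallocationPoint(overallocation=x, increase_pct=100.0 * f * x))
    return points


def parallelization_tradeoff(
    series: Sequence[ParallelObservation],
    per_core_power: float,
    memory: MemoryAllocation,
    facility: FacilityContext,
    usage_factor: float = 1.0,
) -> list[ParallelConfigReport]:
    """Runtime/carbon trade-off of running the same job on more cores.

    Each observation is costed with the full model (n cores at
    ``per_core_power`` W for its measured runtime, memory charged over the
    runtime).  Speedups and footprint changes are relative to the
    smallest core count present; a warning is emitted when that baseline is
    not a single core.
    """
    if not series:
        raise ValidationError("parallel series is empty")
    obs = sorted(series, key=lambda o: o.n_cores)
    counts = [o.n_cores for o in obs]
    if len(set(counts)) != len(counts):
        raise ValidationError(f"duplicate core counts in series: {counts}")
    if obs[0].n_cores != 1:
        warnings.warn(
            f"no single-core observation; using n={obs[0].n_cores} as baseline",
            stacklevel=2,
        )

    def footprint(o: ParallelObservation) -> float:
        resources = TaskResources(
            duration=o.runtime,
            processors=(
                ProcessorAllocation(o.n_cores, per_core_power, usage_factor),
            ),
            memory=memory,
        )
        return compute_footprint(resources, facility).kg_co2e

    base = obs[0]
    base_kg = footprint(base)
    reports = []
    for o in obs:
        kg = footprint(o)
        reports.append(
            ParallelConfigReport(
                n_cores=o.n_cores,
                runtime=o.runtime,
                kg_co2e=kg,
                speedup=base.runtime / o.runtime,
                footprint_change_pct=percent_change(base_kg, kg) if base_kg > 0 else 0.0,
            )
        )
    return reports


def gpu_cpu_breakeven(
    cpu_total_power: float,
    gpu_total_power: float,
    memory: MemoryAllocation | None = None,
) -> float:
    """Speedup a GPU needs over a CPU to break even on carbon.

    Equal footprints require t_cpu * (P_cpu + m) = t_gpu * (P_gpu + m)
    where m is the memory power draw (0 by default — the simple
    approximation scales runtime by the ratio of the processor power
    draws alone).  Returns the required ratio t_cpu / t_gpu; the GPU is
    greener whenever it runs at least that many times faster.
    """
    if not cpu_total_power > 0 or not gpu_total_power > 0:
        raise ValidationError("processor powers must be > 0 W")
    m = memory.power_draw if memory is not None else 0.0
    return (gpu_total_power + m) / (cpu_total_power + m)


def compare_locations(
    baseline_kg: float,
    baseline_facility: FacilityContext,
    options: Sequence[LocationOption],
) -> list[LocationReport]:
    """Re-cost a job's footprint under different facilities and grids.

    The hardware-side energy e = C / (PUE0 * CI0) is location-independent;
    each option's footprint is e * PUE_i * CI_i.  Percent changes therefore
    depend only on the PUE*CI products, not on the job's absolute scale.
    """
    if baseline_kg < 0:
        raise ValidationError(f"baseline_kg must be >= 0, got {baseline_kg!r}")
    denom = baseline_facility.pue * baseline_facility.ci
    if not denom > 0:
        raise ValidationError("baseline facility must have PUE * CI > 0")
    e = baseline_kg / denom
    reports = []
    for opt in options:
        kg = e * opt.facility.pue * opt.facility.ci
        change = (
            percent_change(baseline_kg, kg) if baseline_kg > 0 else 0.0
        )
        reports.append(
            LocationReport(label=opt.label, facility=opt.facility, kg_co2e=kg, change_pct=change)
        )
    return reports


def reduction_between(worse: LocationReport, better: LocationReport) -> float:
    """Percent reduction going from one location to another (positive =
    ``better`` emits less)."""
    if not worse.kg_co2e > 0:
        raise ValidationError("reference location has zero footprint")
    return -percent_change(worse.kg_co2e, better.kg_co2e)
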