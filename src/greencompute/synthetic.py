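"""Synthetic task descriptors and scaling series with known ground truth.

The generator emulates benchmark-catalog entries: each synthetic task is a
(resources, facility) pair whose fields are drawn from documented ranges
spanning the values observed across real bioinformatics benchmarks —
runtimes from seconds to hundreds of thousands of core-hours, memory from
tens of MB to hundreds of GB, carbon intensities from the Swiss to the
Australian grid.  Runtime, memory, and carbon intensity are sampled
log-uniformly (they span four to six orders of magnitude); core count,
per-core power, PUE, and usage factor uniformly.

Everything is driven by a single integer seed through numpy's PCG64
generator, so output is reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import CatalogEntry
from .errors import ValidationError
from .footprint_model import (
    FacilityContext,
    MemoryAllocation,
    ProcessorAllocation,
    TaskResources,
    compute_footprint,
)
from .scaling import ScalingModel

__all__ = [
    "GeneratorSpec",
    "generate_tasks",
    "generate_scaling_series",
    "tasks_to_entries",
]

#: Default sampling ranges, spanning the spreads observed across published
#: benchmarks (runtime 0.002-400,000 h; 1-64 cores; 8-20 W/core;
#: 0.05-262 GB memory; PUE 1.1-1.7; CI 0.012-0.88 kgCO2e/kWh).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "runtime_hours": (0.002, 400_000.0),
    "cores": (1, 64),
    "power_per_core": (8.0, 20.0),
    "memory_gb": (0.05, 262.0),
    "pue": (1.1, 1.7),
    "ci": (0.012, 0.88),
    "usage_factor": (1.0, 1.0),
}

_LOG_UNIFORM = {"runtime_hours", "memory_gb", "ci"}


@dataclass(frozen=True)
class GeneratorSpec:
    """Seeded recipe for a batch of synthetic tasks.

    ``ranges`` overrides any subset of :data:`DEFAULT_RANGES`; bounds must
    be positive with low <= high.
    """

    seed: int
    n: int
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"n must be >= 0, got {self.n}")
        unknown = set(self.ranges) - set(DEFAULT_RANGES)
        if unknown:
            raise ValidationError(f"unknown range keys: {sorted(unknown)}")
        for key, (lo, hi) in self.resolved_ranges().items():
            if not (lo > 0 and hi >= lo):
                if key == "usage_factor" and lo == 0 and hi >= 0:
                    continue  # a usage factor of 0 is legal
                raise ValidationError(f"bad range for {key}: ({lo}, {hi})")

    def resolved_ranges(self) -> dict[str, tuple[float, float]]:
        out = dict(DEFAULT_RANGES)
        out.update(self.ranges)
        return out


def generate_tasks(spec: GeneratorSpec) -> list[tuple[TaskResources, FacilityContext]]:
    """Draw ``spec.n`` synthetic (resources, facility) pairs.

    Deterministic given the seed; every sampled field lies within its
    configured range.
    """
    rng = np.random.default_rng(spec.seed)
    ranges = spec.resolved_ranges()

    def draw(key: str) -> float:
        lo, hi = ranges[key]
        if lo == hi:
            return float(lo)
        if key in _LOG_UNIFORM:
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return float(rng.uniform(lo, hi))

    pairs = []
    for _ in range(spec.n):
        lo_c, hi_c = ranges["cores"]
        n_cores = int(rng.integers(int(lo_c), int(hi_c) + 1))
        resources = TaskResources(
            duration=draw("runtime_hours"),
            processors=(
                ProcessorAllocation(
                    n_cores=n_cores,
                    power_per_core=draw("power_per_core"),
                    usage_factor=draw("usage_factor"),
                ),
            ),
            memory=MemoryAllocation(size_gb=draw("memory_gb")),
        )
        facility = FacilityContext(pue=draw("pue"), ci=draw("ci"), region="synthetic", facility="synthetic")
        pairs.append((resources, facility))
    return pairs


def generate_scaling_series(
    model: ScalingModel,
    base_kg: float,
    sizes: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Footprints following a known scaling law, optionally with noise.

    kg(size) = base_kg * (size / reference)^exponent * eps, where eps is
    multiplicative log-normal noise with relative scale ``noise_sd``
    (footprints are positive and span decades, so noise is multiplicative).
    ``noise_sd=0`` gives the exact law.
    """
    if base_kg <= 0:
        raise ValidationError(f"base_kg must be > 0, got {base_kg!r}")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd!r}")
    sizes = list(sizes)
    if any(s <= 0 for s in sizes):
        raise ValidationError("all sizes must be > 0")
    rng = np.random.default_rng(seed)
    points = []
    for s in sizes:
        kg = base_kg * (s / model.reference_size) ** model.exponent
        if noise_sd > 0:
            kg *= float(np.exp(rng.normal(0.0, noise_sd)))
        points.append((float(s), float(kg)))
    return points


def tasks_to_entries(
    pairs: Sequence[tuple[TaskResources, FacilityContext]],
) -> list[CatalogEntry]:
    """Render synthetic tasks as catalog entries (synthetic rows).

    The printed footprint is the model's own output, and the hardware
    fields are fully populated, so reloaded entries reproduce their
    footprints exactly.  Runtimes are serialized at full float precision to
    keep the round trip bit-exact.
    """
    entries = []
    for i, (res, fac) in enumerate(pairs):
        if len(res.processors) != 1:
            raise ValidationError("catalog rows describe single-allocation tasks")
        proc = res.processors[0]
        fp = compute_footprint(res, fac)
        entries.append(
            CatalogEntry(
                task_group="synthetic",
                tool=f"synthetic-task-{i}",
                version="",
                experiment="synthetic benchmark entry",
                runtime=f"{res.duration:.17g} h",
                runtime_kind=res.duration_kind,
                hours=(res.duration, res.duration),
                memory_gb=(res.memory.size_gb, res.memory.size_gb) if res.memory.known else None,
                cores=proc.n_cores,
                power_per_core=proc.power_per_core,
                pue=fac.pue,
                ci=fac.ci,
                printed_kg=(fp.kg_co2e, fp.kg_co2e),
                printed_tree_months=(fp.equivalents.tree_months, fp.equivalents.tree_months),
                printed_km=(fp.equivalents.car_km, fp.equivalents.car_km),
                printed_increase_pct=None,
                scaling=None,
                hardware_provenance="main-text",
                usage_factor=proc.usage_factor,
            )
        )
    return entries
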