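import numpy as np
import pytest

import greencompute as gc


@pytest.fixture(scope="session")
def shipped_catalog():
    return gc.load_catalog()


@pytest.fixture
def global_facility():
    """The default facility: global-average data center on the world grid."""
    return gc.FacilityContext(pue=1.67, ci=0.475)


def make_core_hour_task(core_hours: float, power_per_core: float = 12.0,
                        memory_gb: float = 8.0) -> gc.TaskResources:
    """An aggregated-benchmark task: total core-hours on one pseudo-core."""
    return gc.TaskResources(
        duration=core_hours,
        processors=(gc.ProcessorAllocation(1, power_per_core),),
        memory=gc.MemoryAllocation(memory_gb),
        duration_kind="core-hours",
    )


def random_task(rng: np.random.Generator) -> tuple[gc.TaskResources, gc.FacilityContext]:
    """One random but valid (resources, facility) pair for property tests."""
    resources = gc.TaskResources(
        duration=float(rng.uniform(0.01, 1000.0)),
        processors=tuple(
            gc.ProcessorAllocation(
                n_cores=int(rng.integers(1, 65)),
                power_per_core=float(rng.uniform(1.0, 50.0)),
                usage_factor=float(rng.uniform(0.0, 1.0)),
            )
            for _ in range(int(rng.integers(1, 3)))
        ),
        memory=gc.MemoryAllocation(size_gb=float(rng.uniform(0.0, 300.0))),
    )
    facility = gc.FacilityContext(
        pue=float(rng.uniform(1.0, 2.5)), ci=float(rng.uniform(0.01, 1.0))
    )
    return resources, facility
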