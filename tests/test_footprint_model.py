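"""Core model: energy breakdown, carbon footprint, memory fraction,
contextual equivalents, and the algebraic invariants of the energy law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import greencompute as gc
from conftest import make_core_hour_task, random_task


def eq2_oracle(resources: gc.TaskResources, facility: gc.FacilityContext) -> float:
    """Literal one-line transcription of the energy law, in kWh."""
    return (
        resources.duration
        * (
            sum(p.n_cores * p.power_per_core * p.usage_factor for p in resources.processors)
            + resources.memory.size_gb * resources.memory.power_per_gb * resources.memory.known
        )
        * facility.pue
        * 0.001
    )


class TestComputeEnergy:
    def test_aggregated_core_hour_benchmark(self, global_facility):
        """300,000 core-hours at 12 W/core with 8 GB at PUE 1.67 needs 7,504.98 kWh."""
        e = gc.compute_energy(make_core_hour_task(300_000), global_facility)
        assert e.total_kwh == pytest.approx(7504.98, rel=1e-9)
        assert e.compute_kwh == pytest.approx(300_000 * 12 * 1.67e-3, rel=1e-12)
        assert e.memory_kwh == pytest.approx(300_000 * 8 * 0.3725 * 1.67e-3, rel=1e-12)

    def test_unit_case(self):
        res = gc.TaskResources(1.0, (gc.ProcessorAllocation(1, 100.0),))
        e = gc.compute_energy(res, gc.FacilityContext(pue=1.0, ci=1.0))
        assert e.total_kwh == pytest.approx(0.1, rel=1e-12)

    def test_zero_duration(self, global_facility):
        res = gc.TaskResources(0.0, (gc.ProcessorAllocation(1, 100.0),),
                               gc.MemoryAllocation(8.0))
        e = gc.compute_energy(res, global_facility)
        assert e.total_kwh == 0.0
        assert e.memory_fraction == 0.0

    def test_breakdown_sums(self, global_facility):
        e = gc.compute_energy(make_core_hour_task(1000.0), global_facility)
        assert e.total_kwh == pytest.approx(e.compute_kwh + e.memory_kwh, rel=1e-12)
        assert e.memory_fraction == pytest.approx(e.memory_kwh / e.total_kwh, rel=1e-12)


class TestComputeFootprint:
    def test_phylogenomics_benchmark(self, global_facility):
        """300,000 core-hours, 12 W/core, 8 GB -> 3,565 kgCO2e as published."""
        fp = gc.compute_footprint(make_core_hour_task(300_000), global_facility)
        assert fp.kg_co2e == pytest.approx(3564.87, abs=0.01)
        assert abs(fp.kg_co2e - 3565) / 3565 < 1e-3

    def test_avian_genome_benchmark(self, global_facility):
        fp = gc.compute_footprint(make_core_hour_task(367_920), global_facility)
        assert fp.kg_co2e == pytest.approx(4371.95, abs=0.01)

    def test_zero_carbon_intensity(self):
        fp = gc.compute_footprint(
            make_core_hour_task(1000.0), gc.FacilityContext(pue=1.67, ci=0.0)
        )
        assert fp.kg_co2e == 0.0

    def test_unknown_memory_is_flagged_and_excluded(self, global_facility):
        res = gc.TaskResources(
            10.0, (gc.ProcessorAllocation(1, 100.0),), gc.MemoryAllocation.unknown()
        )
        fp = gc.compute_footprint(res, global_facility)
        assert "memory_excluded" in fp.flags
        assert fp.energy.memory_kwh == 0.0
        with_mem = gc.TaskResources(10.0, (gc.ProcessorAllocation(1, 100.0),))
        assert "memory_excluded" not in gc.compute_footprint(with_mem, global_facility).flags


class TestMemoryEnergyFraction:
    def test_no_memory(self):
        res = gc.TaskResources(1.0, (gc.ProcessorAllocation(1, 50.0),))
        assert gc.memory_energy_fraction(res) == 0.0

    def test_constructed_37_percent(self):
        """63 W of cores + 37 W of memory -> 37% of total energy in memory."""
        res = gc.TaskResources(
            1.0, (gc.ProcessorAllocation(1, 63.0),),
            gc.MemoryAllocation(size_gb=37.0, power_per_gb=1.0),
        )
        assert gc.memory_energy_fraction(res) == pytest.approx(0.37, rel=1e-12)

    def test_sixteen_core_hand_arithmetic(self):
        res = gc.TaskResources(
            1.0, (gc.ProcessorAllocation(16, 7.5),), gc.MemoryAllocation(100.0)
        )
        assert gc.memory_energy_fraction(res) == pytest.approx(37.25 / 157.25, rel=1e-12)

    def test_all_power_zero_is_undefined(self):
        res = gc.TaskResources(
            1.0, (gc.ProcessorAllocation(1, 10.0, usage_factor=0.0),),
            gc.MemoryAllocation(0.0),
        )
        with pytest.raises(gc.ValidationError):
            gc.memory_energy_fraction(res)

    def test_invariant_under_duration_pue_ci(self, global_facility):
        """f depends only on the power split, not t, PUE, or CI."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            res, _ = random_task(rng)
            if res.processor_power + res.memory.power_draw == 0:
                continue
            f = gc.memory_energy_fraction(res)
            scaled = gc.TaskResources(res.duration * 7, res.processors, res.memory)
            assert gc.memory_energy_fraction(scaled) == f
            e = gc.compute_energy(res, gc.FacilityContext(pue=2.4, ci=0.9))
            if e.total_kwh > 0:
                assert e.memory_fraction == pytest.approx(f, rel=1e-12)


class TestContextualize:
    def test_car_km_for_published_footprints(self):
        assert gc.contextualize(3564.87).car_km == pytest.approx(20370.7, abs=0.1)
        assert gc.contextualize(4371.95).car_km == pytest.approx(24982.6, abs=0.1)

    def test_zero(self):
        eq = gc.contextualize(0.0)
        assert (eq.tree_months, eq.tree_years, eq.car_km) == (0.0, 0.0, 0.0)

    def test_tree_year_is_twelve_tree_months(self):
        eq = gc.contextualize(100.0)
        assert eq.tree_years == pytest.approx(eq.tree_months / 12, rel=1e-12)
        assert eq.tree_months == pytest.approx(100 / 0.917, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(gc.ValidationError):
            gc.contextualize(-1.0)


class TestValidation:
    @pytest.mark.parametrize(
        "build",
        [
            lambda: gc.TaskResources(-1.0, (gc.ProcessorAllocation(1, 10.0),)),
            lambda: gc.MemoryAllocation(-4.0),
            lambda: gc.ProcessorAllocation(0, 10.0),
            lambda: gc.ProcessorAllocation(1, 0.0),
            lambda: gc.ProcessorAllocation(1, 10.0, usage_factor=1.5),
            lambda: gc.FacilityContext(pue=0.9, ci=0.475),
            lambda: gc.FacilityContext(pue=1.67, ci=-0.1),
            # aggregated core-hours must be a single pseudo-core
            lambda: gc.TaskResources(10.0, (gc.ProcessorAllocation(2, 10.0),),
                                     duration_kind="core-hours"),
        ],
    )
    def test_invalid_inputs_rejected(self, build):
        with pytest.raises(gc.ValidationError):
            build()


class TestModelInvariants:
    def test_oracle_equivalence_on_random_tasks(self):
        """The modular implementation agrees with a literal transcription of
        the energy law on 1,000 random tasks to 1e-12 relative."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            res, fac = random_task(rng)
            expected = eq2_oracle(res, fac)
            got = gc.compute_energy(res, fac).total_kwh
            assert got == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_linearity_in_duration_pue_ci(self, seed):
        """Doubling t, PUE, or CI exactly doubles E (and C for CI)."""
        rng = np.random.default_rng(seed)
        res, fac = random_task(rng)
        base = gc.compute_footprint(res, fac)
        double_t = gc.TaskResources(res.duration * 2, res.processors, res.memory)
        assert gc.compute_energy(double_t, fac).total_kwh == pytest.approx(
            2 * base.energy.total_kwh, rel=1e-12, abs=1e-300
        )
        double_pue = gc.FacilityContext(pue=fac.pue * 2, ci=fac.ci)
        assert gc.compute_energy(res, double_pue).total_kwh == pytest.approx(
            2 * base.energy.total_kwh, rel=1e-12, abs=1e-300
        )
        double_ci = gc.FacilityContext(pue=fac.pue, ci=fac.ci * 2)
        assert gc.compute_footprint(res, double_ci).kg_co2e == pytest.approx(
            2 * base.kg_co2e, rel=1e-12, abs=1e-300
        )

    def test_processor_additivity_memory_counted_once(self, global_facility):
        """Energy of a two-allocation task = sum of single-allocation tasks
        with the memory split to zero in one of them (memory charged once)."""
        cpu = gc.ProcessorAllocation(16, 7.5, label="cpu")
        gpu = gc.ProcessorAllocation(1, 300.0, label="gpu")
        mem = gc.MemoryAllocation(64.0)
        both = gc.TaskResources(5.0, (cpu, gpu), mem)
        only_cpu = gc.TaskResources(5.0, (cpu,), mem)
        only_gpu = gc.TaskResources(5.0, (gpu,), gc.MemoryAllocation(0.0))
        e_both = gc.compute_energy(both, global_facility).total_kwh
        e_split = (
            gc.compute_energy(only_cpu, global_facility).total_kwh
            + gc.compute_energy(only_gpu, global_facility).total_kwh
        )
        assert e_both == pytest.approx(e_split, rel=1e-12)
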