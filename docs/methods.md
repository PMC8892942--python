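# Methods

## The energy and carbon model

A job's carbon footprint is modeled in two stages. Energy:

```
E [kWh] = t × (Σ_i n_c,i · P_c,i · u_c,i + n_m · P_m) × PUE × 0.001
```

and carbon: `C = E × CI`. The model's assumptions, and what they imply:

- **Power is allocation-based.** Cores are assumed fully used
  (`u_c = 1` by default), and memory draws power in proportion to what is
  *allocated*, not touched (`P_m = 0.3725` W/GB). Both assumptions bias
  the estimate upward for idle resources; that is intentional, since
  reserved resources are unavailable to others.
- **Memory is charged once per job**, however many cores run: the core
  count multiplies only the processor term.
- **Heterogeneous jobs** (CPU + GPU) are one task with several processor
  allocations summed inside the parenthesis; the model is agnostic to
  processor kind, and the usage factor applies uniformly to CPUs and
  GPUs (whether GPU utilization is really comparable is an open modeling
  question; we document rather than resolve it).
- **Aggregated benchmarks** reported only as total core-hours (e.g.
  "300,000 h") are modeled as one pseudo-core (`n_c = 1`) running for the
  stated core-hours, with memory charged over that full duration. This
  convention reproduces the published large-scale phylogenetics
  footprints (3,565 and 4,372 kgCO2e) to within 0.01%.
- **Out of scope:** idle power, dynamic voltage scaling, per-process
  attribution on shared nodes, embodied/manufacturing carbon, live grid
  feeds.

## Constants and reference tables

All constants live in a bundled, versioned YAML file
(`src/greencompute/data/reference_data.yaml`) and are exposed read-only:
memory power density 0.3725 W/GB; Wh→kWh factor 0.001; car emissions
0.175 kgCO2e/km; tree sequestration 0.917 kgCO2e per tree-month
(tree-year = 12 tree-months exactly); default core power 12 W (a database
average, used when a benchmark reports no hardware); default usage factor
1. Carbon intensities: global 0.475, Australia 0.88, United States 0.453,
United Kingdom 0.253, Switzerland 0.012 kgCO2e/kWh. PUEs: global average
1.67, Google Cloud 1.11, Azure 1.125, AWS 1.2. Keys are lower-case
kebab-case with documented aliases (`uk` = `united-kingdom`).

One known inconsistency is kept visible rather than patched: published
tree-month equivalents of large footprints only reproduce with an
unrounded sequestration constant near 11/12 kgCO2e (3,564.87/0.9167 →
3,889), while the printed constant 0.917 yields 3,888. The registry
stores the printed 0.917 as the default and 11/12 as
`tree_month_kg_unrounded`; golden tests pin the car-km equivalents, which
reproduce exactly with 0.175.

The processor catalog carries two entries with powers stated in the
primary source (Xeon E5-2683, 16 cores / 120 W; Tesla V100, 300 W) and
three convenience entries (Tesla T4, Tesla P100, Xeon Gold 6142) whose
powers are vendor TDP figures, flagged `provenance: vendor` and excluded
from golden-value tests.

## Scenario analyses

- **Memory over-allocation.** "k-fold over-allocation" means reserving
  `(1+k)×` the required memory (this convention, not `k×`, reproduces the
  published +30% for a 6% memory fraction at 5-fold). With baseline
  memory energy fraction `f`, the footprint increase is exactly
  `100·f·x` percent; a property test checks the shortcut against full
  model recomputation to 1e-12 relative.
- **Parallelization.** Each observed (cores, runtime) pair is costed with
  the full model; speedups and footprint changes are reported against
  the smallest core count present (with a warning when that is not 1).
  Cores are assumed independently allocated and fully used; non-linear
  power-management effects are assumed away.
- **GPU/CPU break-even.** The default ignores memory (the simple
  power-draw-ratio approximation); passing a memory allocation charges
  it on both sides, pulling the ratio toward 1.
- **Location comparison.** The hardware-side energy
  `e = C/(PUE₀·CI₀)` is location-independent, so option footprints are
  `e·PUEᵢ·CIᵢ` and percent reductions depend only on PUE·CI products.
  Display percentages round half-up to integers.

## Scaling models

Footprints are normalized per unit of work with an explicit unit scale
("per million" is a first-class scale, avoiding 1e6 bookkeeping errors),
and extrapolated as `C' = C · (s'/s_ref)^α` (α = 1 for linear laws; e.g.
α = 1.5 for mixed-model association tests whose time grows as N^1.5 in
the sample size). The long- vs short-read comparison uses the arithmetic
mean of per-tool per-unit ratios — not the ratio of group means, which
would let the slowest tool dominate.

## Benchmark catalog

The shipped CSV transcribes 44 published tool-experiment footprints.
Design choices:

- Quantities printed as ranges (one Bayesian phylogenetics row, one
  memory column) are stored as min/max pairs; ranged footprints are
  excluded from relative-increase rebuilds.
- Rows whose hardware was published only in supplementary material carry
  `hardware_provenance=supplementary` with empty hardware fields; users
  can fill them in to unlock recomputation. Only the two core-hour
  phylogenetics rows are complete (`main-text`), and those two are golden
  tests (deviation < 0.5%, the rounding envelope of the printed
  precision).
- Two molecular-dynamics rows report no memory; they carry a
  `memory_excluded` flag through to reports instead of a silent 0 GB.
- Printed-vs-recomputed comparison is a report, never an assertion; the
  rebuilt "increase vs baseline" columns are compared to the printed ones
  with a ±2-point / 2%-relative tolerance, and mismatches (which arise
  because the printed columns were computed from unrounded footprints)
  are flagged, not hidden.

## Synthetic data

The generator draws (resources, facility) pairs from documented ranges
spanning the catalog's observed spreads: runtime 0.002–400,000 h, 1–64
cores, 8–20 W/core, 0.05–262 GB memory, PUE 1.1–1.7, CI 0.012–0.88.
Runtime, memory, and CI are log-uniform (they span 4–6 decades); the
rest uniform; usage factor fixed at 1 by default. Scaling series are
generated as `base_kg · (s/s_ref)^α` with multiplicative log-normal
noise (footprints are positive and span decades). All randomness flows
through numpy's seeded PCG64 generator.

What the synthetic stage does *not* emulate: correlations between fields
(real memory-hungry tools also tend to run long), reporting noise in
published runtimes, or actual workload behavior. Passing tests therefore
demonstrate the accounting pipeline's correctness and numerical
stability, not the realism of any particular footprint.

## Numerical choices and problem sizes

Full floating point everywhere; rounding only in the table renderer
(half-up: 2 significant figures below 1 kg, 2 decimals below 100 kg,
whole kilograms above; equivalents become integers above 10). Machine
formats (CSV/JSON) always carry unrounded values. Property tests run on
1,000 random tasks for the energy-law oracle and 200 for the
over-allocation shortcut; exponent recovery uses 20–50 log-spaced sizes.
These sizes keep the whole suite under a few seconds while exercising
4–6 decades of parameter space.

## Known limitations

- Per-core power defaults to a single 12 W average; real draws vary ~2×
  by microarchitecture and frequency.
- PUE and CI are static annual averages; time-of-day and seasonal grid
  variation is out of scope.
- The catalog's non-reproducible rows are data, not evidence: their
  printed footprints cannot be independently verified from the shipped
  fields alone.
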