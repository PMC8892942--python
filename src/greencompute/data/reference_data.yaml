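# greencompute reference data, schema v1.
# Constants and lookup tables used by the footprint model. Users may supply
# an override file with the same schema via --reference-data / ReferenceData.from_file.
schema_version: 1

constants:
  # Power drawn per GB of allocated memory, W/GB.
  memory_power_per_gb: 0.3725
  # Wh -> kWh.
  kwh_per_wh: 0.001
  # Average European car, kgCO2e per km.
  car_emission_kg_per_km: 0.175
  # CO2e sequestered by one mature tree in one month, kgCO2e.
  tree_month_kg: 0.917
  # Unrounded candidate for the same constant (11/12 kgCO2e); some published
  # tree-month figures only reproduce with this value. Kept for reference,
  # not used by default.
  tree_month_kg_unrounded: 0.9166666666666666
  # Months per tree-year (exact).
  tree_months_per_year: 12
  # Default per-core CPU power draw, W (database average).
  default_core_power: 12.0
  # Default core usage factor (cores assumed fully used).
  default_usage_factor: 1.0

# Regional carbon intensity of electricity production, kgCO2e per kWh.
carbon_intensity:
  global: 0.475
  australia: 0.88
  united-states: 0.453
  united-kingdom: 0.253
  switzerland: 0.012

carbon_intensity_aliases:
  world: global
  average: global
  au: australia
  us: united-states
  usa: united-states
  uk: united-kingdom
  gb: united-kingdom
  ch: switzerland

# Power usage effectiveness of computing facilities (total facility energy
# over energy delivered to the hardware; 1.0 is ideal).
pue:
  global-average: 1.67
  google-cloud: 1.11
  azure: 1.125
  aws: 1.2

pue_aliases:
  global: global-average
  average: global-average
  local: global-average
  google: google-cloud
  gcp: google-cloud
  microsoft-azure: azure
  amazon: aws
  amazon-web-services: aws

# Processor power-draw catalog. provenance=vendor entries carry manufacturer
# TDP figures and are excluded from golden-value tests.
processors:
  - name: xeon-e5-2683
    kind: cpu
    core_count: 16
    total_power: 120.0
    provenance: primary
  - name: tesla-v100
    kind: gpu
    core_count: 1
    total_power: 300.0
    provenance: primary
  - name: tesla-t4
    kind: gpu
    core_count: 1
    total_power: 70.0
    provenance: vendor
  - name: tesla-p100
    kind: gpu
    core_count: 1
    total_power: 250.0
    provenance: vendor
  - name: xeon-gold-6142
    kind: cpu
    core_count: 16
    total_power: 150.0
    provenance: vendor
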