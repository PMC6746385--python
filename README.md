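# epicens

Desk-scale analysis of parameterization-induced uncertainty in an
EPIC-style gridded crop-model ensemble.

A synthetic gridded world and a minimal daily crop–soil simulator with six
switchable setup domains (cultivars, soil data, soil handling,
nutrient-cycling coefficients, hydrologic coefficients, crop management)
stand in for a multi-model ensemble.  On top of them the package implements
the full analysis stack:

- **`epicens.world`** — synthetic study region: 0.5°-style cells with daily
  weather (seasonal sinusoid + AR(1) noise on a 360-day calendar), layered
  soils, N/P application rates, rainfed/irrigated harvested areas, country
  and climate-region labels, growing seasons, and country-level "reported"
  yield series with a technology trend, noise, and data-quality flags.
- **`epicens.config`** — the `SetupConfig` parameter switchboard and five
  shipped presets (`boku`, `iiasa`, `tamu`, `gepic`, `pepic`); two-anchor
  sigmoid utilities; YAML round trip.
- **`epicens.simulator`** — daily heat-unit phenology, radiation-driven
  potential growth, curve-number bucket water balance, first-order N/P
  cycling, the single-most-limiting-stress rule, and harvest-index yield
  formation; three management scenarios (`default`, `fullharm`,
  `harm-suffN`) × two water regimes.
- **`epicens.aggregation`** — area-weighted national/global yield series
  and ensemble-mean confidence bands.
- **`epicens.metrics`** — CV of long-term means across members (`cv_av`),
  mean-normalized time-series CV (`cv_t`), mean error, pairwise/median
  Pearson correlation, critical-r thresholds, significance fractions,
  quantile tables.
- **`epicens.benchmarking`** — moving-mean detrending of reported yields,
  country quality filters, per-country scoring of every ensemble member,
  multi-model-mean evaluation, top producers.
- **`epicens.permutation`** — the 2^6 factorial that splices the six setup
  domains between two presets, with per-domain paired-effect attribution.
- **`epicens.drivers`** — relates per-cell disagreement to fertilizer rate
  (OLS capped at 200 kg N/ha), climate region and cultivar-agreement class.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence suites, simulator invariants, planted-effect recovery, the
qualitative harmonization pattern); the remaining files are per-module unit
and property tests.

## Command line

```sh
epicens generate-world --cells 150 --countries 12 --years 20 --seed 1 --out out/world
epicens run-ensemble  --world out/world --out out/yields.nc --csv out/yields.csv
epicens metrics       --cube out/yields.nc --scenario fullharm --water rainfed --out out/metrics
epicens benchmark     --world out/world --cube out/yields.nc --out out/bench
epicens permute       --world out/world --out out/perm
epicens drivers       --world out/world --cube out/yields.nc --out out/drivers
epicens protocol      --seed 7 --cells 150 --years 20 --out out/protocol
```

`protocol` runs the whole pipeline (five presets × six management
scenarios, agreement metrics, benchmarking, the 64-way permutation, driver
regressions) from one seed and writes a JSON manifest with checksums of
every output.  All commands exit with code 2 on configuration errors.

Every stochastic component derives its stream from the top-level seed via
domain-separated hashing (`epicens.seeding`), so stages are independently
reproducible.

## File formats

- Yield cubes: NetCDF with dims `(config, scenario, water, year, cell)`
  and a mandatory `units = "t ha-1"` attribute, or equivalent long CSV.
  Year 1 carries a `year_valid = False` coordinate (incomplete first
  growing season) and is excluded from all downstream means.
- Worlds: `world.nc` (gridded variables), `countries.csv`,
  `world_params.json` (generator parameters incl. seed).
- All analysis tables: tidy CSV.
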