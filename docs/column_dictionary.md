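# Flux-table column dictionary

`crossflux` reads and writes UTF-8 delimited tables (comma by default; tab
for `.tsv`/`.tab` files). Enum tokens are case-insensitive. Empty cells mean
"not applicable / not reported". This column layout is this package's own
interchange format for compiled flux datasets.

## Mandatory columns

| column | type | values / units |
|---|---|---|
| `record_id` | string | unique identifier of the measurement |
| `ecosystem` | enum | `forest`, `grassland`, `agro_ecosystem`, `desert`, `stream`, `lake`, `ocean_pelagic`, `ocean_benthic` — the *recipient* ecosystem |
| `climate` | enum | `arctic_alpine`, `boreal`, `temperate`, `tropical`, `arid` (marine records keep their source climate; Cold/Warm pooling happens at summary time) |
| `flux_class` | enum | `gpp`, `ecosystem_respiration`, `nep`, `npp`, `secondary_production`, `detritus_stock`, `decomposition_rate`, `decomposition_flux`, `spatial_flow` |
| `value` | float | magnitude in the raw unit described by the basis columns; only `nep` may be negative |
| `mass_basis` | enum | `carbon`, `dry_weight`, `ash_free_dry_weight`, `wet_weight` |
| `spatial_basis` | enum | `per_m2_recipient`, `per_m2_donor`, `per_m3`, `per_m_shoreline`, `per_lake`, `per_stream_reach`, `none` (`none` only for decomposition rates, which carry a time dimension only) |
| `time_basis` | enum | `per_year`, `per_day`, `per_study_period`, `none` (`none` only for detritus stocks) |

## Optional columns

| column | type | meaning |
|---|---|---|
| `study_id` | string | source-study identifier |
| `material_origin` | enum | `primary_producer`, `invertebrate`, `vertebrate`, `poc_doc`, `none` — spatial flows only |
| `material_class` | enum | `terrestrial_plant`, `macroalga`, `invertebrate`, `vertebrate`, `mixed_detritus`, `poc_doc`, `generic` — selects the carbon conversion factor |
| `driver` | enum | `fall_wind`, `leaching`, `current_tides`, `sinking` (passive); `foraging`, `migration`, `life_cycle` (active); `none` for local fluxes |
| `donor_ecosystem` | enum | ecosystem of origin, spatial flows only |
| `study_period_days` | float | required when `time_basis = per_study_period` |
| `carbon_fraction` | float in (0, 1] | study-reported carbon content; overrides the factor table |

## Geometry columns (waterbody metadata)

| column | units | used for |
|---|---|---|
| `lake_area` | m^2 | donor-area and per-lake flows; lake depth from volume |
| `lake_volume` | m^3 | lake mean depth = volume / area |
| `lake_perimeter` | m | measured perimeter (overrides the development-factor approximation) |
| `development_factor` | — (>= 1) | shoreline development factor D_L; 1 = circular |
| `mean_depth` | m | direct water-column depth for per-m^3 values |
| `stream_width` | m | stream donor-area flows (width / 2 rule) |
| `reach_length` | m | per-stream-reach totals |
| `discharge` | m^3 s^-1 | river depth = 0.2 * Q^0.4 |
| `catchment_area` | km^2 | < 1 km^2 triggers the 5 cm depth rule |
| `photic_depth` | m | euphotic-zone depth for pelagic per-m^3 values (100 m fallback) |

## Output-only column

`audit` — JSON list of `[step, multiplier, rule]` triples recording every
harmonization step applied to the record; the product of multipliers times
the raw value equals the harmonized value exactly. Also exportable as a
long-format table (`record_id`, `step_index`, `step_name`, `multiplier`,
`rule`).
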