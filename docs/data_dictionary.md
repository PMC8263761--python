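# Data dictionary

Every table the package reads or writes is plain CSV with a header row;
timestamps are naive local time in ISO-8601 (`YYYY-MM-DDTHH:MM:SS`), hourly.

## Forcing table (`read_forcing_table` / `write_forcing_table`, `synth-forcing`)

| column | units | description |
|---|---|---|
| timestamp | — | hourly, strictly increasing; gaps ≤ 3 h are interpolated on read |
| T | °C | water temperature |
| I0 | μmol photons m⁻² s⁻¹ | incident surface irradiance; 0 outside light hours |
| S | PSU | salinity |
| N_up | μmol-N l⁻¹ | dissolved N of the upstream/boundary water |
| is_light | bool | daylight flag (I0 above the configured threshold) |

## Hourly trajectory table (`simulate`, `run_cycle(record=True)`)

One row per (hour, reactor).

| column | units | description |
|---|---|---|
| time | — | timestamp of the completed hourly step |
| x | — | reactor index along the flow, 1 = most upstream |
| m | gDW l⁻¹ | biomass density |
| N_int | % gN gDW⁻¹ | internal nitrogen quota |
| N_ext | μmol-N l⁻¹ | dissolved N inside the cage |
| N_env | μmol-N l⁻¹ | ambient dissolved N below the cage |

## Cycle / scenario summary (`simulate_summary.csv`, `AnnualSummary.table`)

| column | units | description |
|---|---|---|
| season, Q_p, d | —, l h⁻¹, fraction | scenario identifiers (simulate only) |
| total_production_gDW | gDW | Σ over reactors of (m_f − m0)·V_cage |
| total_n_removed_gN | gN | Σ of (m_f·N_int,f − m0·N_int0)·V_cage/100 |
| areal_productivity_gDW_m2_day | gDW m⁻² day⁻¹ | production / (area × reactors × days) |
| areal_n_sequestration_gN_m2_day | gN m⁻² day⁻¹ | N removed / (area × reactors × days) |
| outlet_final_N_env_uM | μmol-N l⁻¹ | ambient N below the last reactor at harvest |

## Farm-design report (`design_report.csv`)

| column | description |
|---|---|
| season | season preset |
| reactors | smallest count meeting the threshold, or `unreachable` |
| area_m2 | reactors × illuminated area per reactor |

## Calibration experiment records (`write_experiments` / `read_experiments`)

`experiments.csv` — one row per cultivation return:

| column | units | description |
|---|---|---|
| id | — | return identifier |
| duration_days | days | cultivation duration |
| m0, m_f | gDW l⁻¹ | stocked and harvested biomass density |
| temp_insitu | bool | temperature series logged in the reactor (vs station) |
| N_ambient | μmol-N l⁻¹ | dissolved N of the pumped water |
| N_int0 | % gN gDW⁻¹ | stocking quota |
| has_insitu_light | bool | whether an in-reactor light record exists |

Per return: `<id>_forcing.csv` (forcing-table layout, ex-situ light) and
optionally `<id>_light_insitu.csv` with one column `I_insitu`
(μmol photons m⁻² s⁻¹, hourly, the irradiance measured inside the reactor).

## Calibration scan tables (`calibration_step1.csv`, `calibration_step2.csv`)

One row per parameter combination: the scanned parameter columns (e.g.
`K_a`; `mu_max`, `K_I`, `lambda_20`), `relerr_<id>` (absolute relative
error of the combination on return `<id>`, fraction) and `rmsre1` /
`rmsre2` (fraction; square root of the mean absolute relative error).

## Sensitivity table (`sensitivity_indices.csv`)

| column | description |
|---|---|
| parameter | model parameter name |
| output | `total_biomass_gDW`, `total_n_removed_gN` or `mean_final_N_env_uM` |
| S1, ST | first-order and total Sobol indices (raw, may be slightly negative) |
| S1_conf, ST_conf | bootstrap confidence half-widths |
| base_n, seed | Saltelli base sample size and seed of the run |
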