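# Column dictionaries

All tables are comma-separated UTF-8 CSV with a mandatory header row and
"." as the decimal separator. Units are fixed by the schema and never
converted. Missing values are empty cells.

## fish.csv — one row per fish per measurement day

| column | type | description |
|---|---|---|
| fish_id | string | fish identifier, unique within the trial |
| tank_id | string | housing tank (biological replicate) |
| day | int ≥ 0 | days since trial start; must be on the trial schedule |
| sex | `male` / `female` | |
| weight_g | float > 0 | body wet weight W, grams |
| fork_length_mm | float > 0 | fork length L, millimetres |

(fish_id, day) must be unique.

## tanks.csv — one row per tank

| column | type | description |
|---|---|---|
| tank_id | string | unique |
| diet_id | string | must exist in diets.csv; exactly one diet per tank |

## diets.csv — one row per diet

| column | type | description |
|---|---|---|
| diet_id | string | unique |
| substitution_pct | float in [0, 100] | % maize substitution |
| dry_matter | float in [0, 100] | g per 100 g diet |
| carbohydrates | float in [0, 100] | g per 100 g diet |
| proteins | float in [0, 100] | g per 100 g diet |
| lipids | float in [0, 100] | g per 100 g diet |
| is_commercial_control | bool | off-the-shelf benchmark feed flag |

carbohydrates + proteins + lipids ≤ dry_matter ≤ 100.

## organs.csv — one row per pooled organ sample (per tank × sex × organ)

| column | type | description |
|---|---|---|
| tank_id | string | |
| sex | `male` / `female` | |
| organ | `liver` / `gonad` / `muscle` | |
| n_fish | int > 0 | fish pooled (default protocol: 10) |
| organ_weight_g | float ≥ 0 | pooled organ wet weight, grams |
| total_body_weight_g | float > 0 | summed body weight of the same fish |
| carbohydrate_mg | float ≥ 0, optional | assayed mass per pooled sample |
| protein_mg | float ≥ 0, optional | |
| lipid_mg | float ≥ 0, optional | |

organ_weight_g < total_body_weight_g.

## feces.csv — one row per tank collection

| column | type | description |
|---|---|---|
| tank_id | string | |
| collection_hours | float > 0 | collection window (default 24) |
| carbohydrate_mg | float ≥ 0 | raw component mass; dry-matter |
| protein_mg | float ≥ 0 | normalisation, if wanted, is the caller's |
| lipid_mg | float ≥ 0 | responsibility |

## rations.csv — one row per tank

| column | type | description |
|---|---|---|
| tank_id | string | |
| carbohydrate_mg_day | float ≥ 0 | component mass in one day's feed dose |
| protein_mg_day | float ≥ 0 | (dose = 2.5 % of total initial tank wet |
| lipid_mg_day | float ≥ 0 | weight per day unless overridden) |

## endpoints.csv — one row per tank × stratum × endpoint × day

| column | type | description |
|---|---|---|
| trial_id | string | |
| diet_id | string | |
| tank_id | string | |
| sex_stratum | `male` / `female` / `pooled` | |
| endpoint_name | string | e.g. RCF, AGR, HSI, GSI, uptake_carbohydrate, liver_protein_conc |
| day | int | measurement day |
| value | float or empty | empty = missing, never zero |

## reference.csv — natural-response-variation dataset

| column | type | description |
|---|---|---|
| endpoint_name | string | |
| variety_id | string | non-GM reference variety (≥ 3 per endpoint) |
| trial_id | string | feeding trial the value came from |
| tank_id | string | ≥ 2 tanks per variety |
| sex_stratum | `male` / `female` / `pooled` | |
| value | float | one row per fish (fish-level) or per tank (tank-level) |

## equivalence.csv — output of the equivalence stage

endpoint_name, sex_stratum, contrast (`GM_vs_NS` / `GM_vs_WT` / `NS_vs_WT`),
scaled_estimate (EL units), ci_low, ci_high, el_absolute (natural scale),
verdict, error (empty unless the endpoint failed).
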