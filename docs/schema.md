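# Claims input schema

The pipeline consumes four flat CSV tables placed in one directory.  All
dates are ISO-8601 calendar dates (`YYYY-MM-DD`); durations are computed in
integer days.  `haeclaims.ClaimsDataset.from_csv(dir)` reads and validates
them; `haeclaims simulate`/`haeclaims fixtures` write them.

## patients.csv

| column           | type   | notes                                             |
|------------------|--------|---------------------------------------------------|
| patient_id       | string | unique key referenced by every other table        |
| sex              | string | `F` / `M`                                         |
| birth_year       | int    | age at index = index year − birth_year            |
| region           | string | e.g. `EAST`, `MIDWEST`, `SOUTH`, `WEST`           |
| payer            | string | e.g. `COMMERCIAL`, `SELF_INSURED`, `MEDICAID`     |
| insurance_type   | string | e.g. `PPO`, `HMO`, `POS`, `OTHER`                 |
| pharmacy_benefit | string | `Y` / `N`                                         |

## enrollment.csv

| column     | type | notes                                        |
|------------|------|----------------------------------------------|
| patient_id | string | |
| span_start | date | first covered day of the span (inclusive)    |
| span_end   | date | last covered day of the span (inclusive)     |

Spans may not have `span_end < span_start`.  Gaps between spans of at most
`grace_days` uncovered days (default 0) are bridged when computing
continuous enrollment.

## pharmacy.csv

| column      | type  | notes                                                       |
|-------------|-------|-------------------------------------------------------------|
| patient_id  | string | |
| fill_date   | date  | |
| product     | string | one of `CINRYZE`, `BERINERT`, `ICATIBANT`, `ECALLANTIDE`, `ANDROGEN`, `TXA` |
| quantity_iu | float | IU dispensed; populated only for the two C1-INH(IV) brands  |
| days_supply | int   | optional; when absent, terminal coverage defaults to 7 days |

Only `CINRYZE`, `BERINERT`, `ICATIBANT`, `ECALLANTIDE` are HAE-specific
(index-eligible); androgens and tranexamic acid are carried as legacy
therapy and never set the index date.

## medical.csv

| column       | type   | notes                                           |
|--------------|--------|-------------------------------------------------|
| patient_id   | string | |
| service_date | date   | |
| dx1..dx3     | string | ICD-9-CM diagnosis codes (dot optional)         |
| proc1..proc3 | string | procedure codes; CVAD events use the symbolic set |
| setting      | string | `INPATIENT`, `ED`, `OFFICE`, `OTHER`            |

The HAE diagnosis is ICD-9-CM `277.6`, matched dot-insensitively on any
diagnosis position.  CVAD procedure and complication codes default to the
symbolic vocabulary in `haeclaims/data/cvad_codes.csv` (`INSERT_PORT`,
`REMOVE_PORT`, `REPAIR_PORT`, `REPLACE_PART`, `REPLACE_FULL`,
`DX_MECH_COMPL`, `DX_CVC_INFECT_OTHER`, `DX_CVC_INFECT_LOCAL`); map real
CPT/ICD-9 codes onto that table for production data.  The Charlson/Deyo
diagnosis mapping ships in `haeclaims/data/deyo_icd9.csv`.
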