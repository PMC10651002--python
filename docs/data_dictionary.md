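# Data dictionary

Both inputs are strict UTF-8, comma-delimited CSV with a header row.
All dates are ISO-8601 (`YYYY-MM-DD`); one format cohort-wide, no
per-row sniffing. Booleans are `True`/`False`. Empty cells denote
missing values.

## `cohort.csv` — one row per pregnancy

| column | type | description |
|---|---|---|
| `woman_id` | string | opaque identifier, unique within the table |
| `enrollment_date` | date | cohort enrollment |
| `us_ga_weeks` | float | ultrasound GA at the scan, weeks (requires `us_date`) |
| `us_date` | date | ultrasound scan date |
| `lmp_date` | date | last menstrual period |
| `fundal_height_cm` | float | fundal height at enrollment, centimeters |
| `recall_months` | int | maternal recall of GA, whole months |
| `self_visits_enroll` | int ≥ 0 | self-reported ANC visits before enrollment |
| `delivery_date` | date | delivery; empty iff lost to follow-up |
| `outcome` | enum | `live_birth`, `stillbirth`, `miscarriage`, `unknown` |
| `ltfu` | bool | lost to follow-up before delivery |
| `ltfu_date` | date | censoring date; present iff `ltfu` |
| `age_years` | float | age at conception (covariate) |
| `district` | string | district of residence (covariate) |
| `literate` | bool | can read and write (covariate) |
| `wealth_q` | int 1–5 | wealth quintile, consumed as given (covariate) |
| `ethnicity` | string | ethnic group (covariate) |
| `primiparous` | bool | first pregnancy (covariate) |
| `hist_stillbirth` | bool | history of stillbirth (covariate) |
| `hist_preterm` | bool | history of preterm birth (covariate) |
| `walk_minutes` | float | walking time to nearest facility (covariate) |

The first twelve columns are mandatory; unknown extra columns are
preserved as covariates. Invariants enforced on read: unique
`woman_id`; `ltfu` records have `ltfu_date` and no `delivery_date`
(and vice versa); `self_visits_enroll ≥ 0`; an ultrasound GA requires
a scan date.

## `visits.csv` — one row per ANC contact

| column | type | description |
|---|---|---|
| `woman_id` | string | must join to `cohort.csv` |
| `visit_date` | date | may be empty only for `self_report` rows |
| `source` | enum | `chart_prospective`, `chart_retrospective`, `self_report` |

Chart-sourced rows must be dated. Records arrive pre-linked across
facilities; the package performs no deduplication beyond collapsing
same-day chart rows for the same woman.
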