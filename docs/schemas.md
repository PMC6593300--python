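# Canonical flow schemas

All flows are headered CSV, UTF-8, ISO-8601 dates, one record type per
file, linked by an opaque anonymized `subject_id`. List-valued fields
use `|` as the separator. The real record layouts of regional
administrative flows are proprietary; these schemas are this package's
own stable interchange format.

## registry.csv — population registry + co-pay fee exemptions
| column | type | notes |
|---|---|---|
| subject_id | string | unique within the registry |
| birth_year | int | ≤ last observation year |
| sex | `F` / `M` | |
| area | string | geographic area label (`Area1`, `Area2`, …) |
| gp_id | string | general practitioner identifier, may be empty |
| exemption_codes | `\|`-list | pathology co-pay exemption codes (standing evidence) |

## discharges.csv — hospital discharge forms
| column | type | notes |
|---|---|---|
| subject_id | string | |
| admission_date / discharge_date | date | admission ≤ discharge |
| regime | `ordinary` / `day_hospital` / `day_surgery` | only ordinary admissions feed the pre-chronic level rules |
| admission_type | `planned` / `unplanned` | carried as input, not derived |
| area_of_care | `surgical` / `medical` | carried as input, not derived |
| diagnoses | `\|`-list | ICD-9-CM codes without dots, principal first; non-empty |
| is_birth_event | bool | delivery or healthy-newborn stay; never counts toward level rules |
| cost | float ≥ 0 | |

## drugs.csv — outpatient drug prescriptions
`subject_id, dispense_date, atc_code, cost` — ATC classification code,
matched by rule prefixes.

## outpatient.csv — visits / laboratory / imaging
`subject_id, service_date, branch_code, cost` — specialty branch label
(e.g. `oncology`).

## deaths.csv — mortality
`subject_id, death_date` — at most one row per subject.

## er.csv — emergency-room accesses
`subject_id, access_date`.

## pathology_registers.csv — GP-reported pathology registers
`subject_id, register, year` with `register` ∈
{`heart_failure`, `diabetes`}.

## home_care_registers.csv — home/community assistance
`subject_id, register, year` with `register` = `home_care`.

Rows violating an invariant (reversed dates, empty diagnosis list,
negative cost, unknown enumeration value) are collected into a rejects
report with row number and reason; they are never silently dropped.
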