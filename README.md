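# ipp-model

Claims-based stratification of a healthcare population into complexity
levels with the **Individual Profile of Pathology (IPP)** algorithm,
plus the utilization / spending / progression analytics built on top of
it and a calibrated synthetic administrative-data generator.

The package is aimed at health-services researchers and public-health
analysts who work with linked administrative flows (population registry
and co-pay fee exemptions, hospital discharge forms, drug prescriptions,
outpatient services, mortality, emergency-room accesses, pathology and
home-care registers) and need a reproducible, configurable way to
segment a population by chronicity and complexity — in the spirit of the
Kaiser Permanente pyramid — without access to clinical records.

## The algorithm

**Step 1 — macro-category classification.** One configurable rule per
disease macro-category is evaluated against every subject's linked
events over a two-year observation window. A rule is an OR over evidence
channels (exemption codes, ICD-9-CM diagnosis ranges, ATC drug prefixes,
outpatient specialty branches, register flags) and over events within
each channel; e.g. a subject is *neoplastic* if they received oncology
outpatient treatment, and/or took antineoplastic drugs (ATC `L01`/`L02`),
and/or carried a tumor discharge diagnosis (ICD-9-CM 140–208). The
result is the **patient matrix**: one row per subject, 18 binary columns
— 17 macro-categories in descending severity order (severe disability,
psychiatric disorders, drug addictions, transplants, chronic renal
insufficiency, HIV/AIDS, neoplasm, diabetes, cardiovascular, COPD,
gastro-enteropathy, neuropathy, autoimmune, endocrine-metabolic, rare
diseases, pregnancy, other residual) plus a death flag.

**Step 2 — profile scoring and levels.** A subject's chronic categories
form their IPP, scored with binary positional weights

```
w(r) = 2^(17 − r),          score(P) = Σ_{c ∈ P} w(rank(c))
```

so distinct profiles always get distinct scores and any single more
severe category outweighs every less severe combination (a
cardiovascular + neoplasm + gastro profile scores 1344, above the 448 of
cardiovascular + COPD + gastro). Each distinct profile's score is then
weighted for its carriers' observed mortality, `adj = score · (1 + m)`,
and the quartiles of the distribution of adjusted scores over *distinct*
profiles cut the chronic population into chronicity levels I–IV. The
full model assigns every subject one of nine mutually exclusive levels:

| level | rule |
|---|---|
| Healthy | no chronic category, no hospitalization (births excluded) |
| Death for acute cause | died in-window without chronic disease |
| Early symptoms | non-chronic, ≥1 ordinary admission in one of the two years |
| First diagnostic tests | non-chronic, ordinary admissions in both years |
| Chronic I–IV | chronic profile, by adjusted score vs. the quartile cut-points |
| Terminal illness | chronic profile + in-window death; keeps its chronic *origin level* |

## Worked example

The synthetic generator's defaults plant the population structure the
model was originally reported on, as raw event flows only. End to end:

```bash
ipp pipeline --seed 42 --n-subjects 50000 --out demo/
```

runs simulate → link → classify → stratify → analyze → report (about
20 s) and writes, among other outputs, `demo/summary.csv`:

```
level,count,pct_of_population,mean_categories
Healthy,26338,52.7,0.06
DeathAcute,76,0.15,0.0
EarlySymptoms,3021,6.0,0.0
FirstDiagnostic,742,1.5,0.0
ChronicI,11004,22.0,1.00
ChronicII,2595,5.2,1.03
ChronicIII,2690,5.4,1.03
ChronicIV,2972,5.9,2.25
Terminal,562,1.1,1.62
```

Read: 39.6% of the population carries a chronic profile (levels I–IV +
Terminal); level I is the largest chronic stratum (22.0%), level IV has
the highest mean number of distinct diagnostic categories (2.25), and
1.1% of the population is terminal — chronic subjects who died in the
window, each retaining the chronic level their adjusted score implies.
`demo/analysis/` holds the per-level hospitalization rates, the
surgical/medical × planned/unplanned demand breakdown, ER-access
prevalence, home-care rates, mean annual spending per stream, and the
9×9 year-over-year progression matrix; `demo/report.md` renders the
headline tables.

Each stage is also available separately (`ipp simulate|link|classify|
stratify|analyze|report`) and as library functions
(`ipp.generate_population`, `ipp.link_subjects`,
`ipp.build_patient_matrix`, `ipp.stratify_population`, …). The rule
table ships as editable YAML (`src/ipp/data/default_rules.yaml`); the
flow CSV schemas are documented in `docs/schemas.md`.

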