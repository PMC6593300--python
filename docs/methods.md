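# Methods

This note documents the model as implemented, the choices made where
the method description leaves room, what the synthetic generator does
and does not emulate, and the numerical conventions.

## The two-step model

**Step 1.** Classification is a pure OR-of-ORs: a subject belongs to a
macro-category as soon as any in-window event matches any evidence
channel of that category's rule. There are no minimum event counts, no
look-back constraints and no channel weighting. Exemption codes sit on
the registry record, carry no date, and are treated as standing
evidence valid for any window. ICD-9-CM codes are stored without dots;
range entries (`"140-208"`) match the first three characters
numerically, other entries match as string prefixes (`"V42"`). The
pathology registers (heart failure, diabetes) are wired as an extra OR
channel of the cardiovascular and diabetes rules; remove the
`register_flags` entries in the rule YAML to restrict them to
validation. The original classification system's full code table is not
public; the shipped rule table is an editable, documented default — the
algorithm is the channel structure, the codes are configuration.

**Step 2.** With ranks r = 1 (most severe) … 17 and binary weights
w(r) = 2^(17−r), the score is a bijection of the chronic category set
and orders profiles lexicographically by severity, which is exactly the
property the method's worked comorbidity comparison requires. Fifteen
categories are chronic; pregnancy and the residual class carry no
weight and never make a subject chronic. Death contributes no score; it
acts only in the level rules.

Choices made where the method is under-specified (all configurable or
isolated in one function):

* **Mortality weighting.** "Weighted for the proportion of deaths" is
  implemented as `adj(p) = score(p) · (1 + m(p))` with `m(p)` the
  death fraction among carriers of the distinct profile `p`. The form
  is the identity at zero mortality, order-preserving at equal
  mortality, and bounded by a factor 2.
* **Quartile basis.** Quartiles (linear interpolation) are taken over
  the multiset of *distinct-profile* adjusted scores, each distinct
  profile counted once — not over subjects. Subject-weighted quartiles
  would force near-equal chronic level sizes, which is incompatible
  with the reported strongly unequal level shares (22.2 / 5.1 / 5.3 /
  5.9% of the population); the distinct-profile basis reproduces them.
* **Boundaries.** Chronic levels are the intervals (q1, q2], (q2, q3],
  … with the lowest interval closed below; a degenerate all-equal
  distribution collapses into level I.
* **Pre-chronic levels.** Only ordinary-regime, non-birth admissions
  count. Over a multi-year window: admissions in every year → First
  diagnostic tests; in some but not all years → Early symptoms. Over a
  single-year window (used by the progression analysis, which
  re-stratifies each year separately) the distinction degenerates, so
  repeated admissions (≥2 in the year) stand in for "both years" —
  one admission marks Early symptoms.
* **Terminal.** Any chronic profile plus an in-window death, whatever
  the death cause recorded elsewhere; the origin level is the chronic
  level the adjusted score implies on the same cut-points.

## Analytics conventions

Rates are prevalence-style (subjects with ≥1 qualifying event per
1,000), with admission-count rates as a secondary column — the count
rate is the right scale for "who is hospitalized most", because the
First-diagnostic level is 100% hospitalized *by definition* on the
prevalence scale. Demand counts all three regimes; percentage tables
are closed compositions. Empty strata are reported as missing (NaN),
never as zero. Deaths contribute person-time as full years (no
person-time adjustment anywhere). The progression matrix is
row-conditional over subjects present in both years; subjects who died
in year 1 have no year-2 state and are excluded, year-2-only subjects
are reported as entrants.

## The synthetic generator

The generator emulates eight linked flows over 2013–2014 for two areas
(population split 58/42, mirroring a 138,859-resident two-area cohort)
and plants, as its default study conditions: chronic level shares
22.2 / 5.1 / 5.3 / 5.9% of the population, 1.1% terminal with origin
mix ∝ 6/26/21/48 across levels I–IV, ≈16% multimorbidity among the
chronic, Early-symptoms / First-diagnostic / acute-death shares of
6.0 / 1.5 / 0.15% (not printed anywhere; chosen to sit consistently
with the reported demand shares and hospitalization rates of those
levels), chronic same-level retention ≈84% across years and
pre-chronic worsening ≈40%.

Profiles are planted at the profile-family level, not as independent
per-category coin flips: each chronicity level is represented by six
distinct category combinations drawn from that level's reported
clinical description (level I: one of cardiovascular /
endocrine-metabolic / neuropathy / gastro-enteropathy / COPD, or
COPD+gastro; level II: cardiovascular pairs or diabetes; level III:
three-category combinations or neoplasm alone; level IV: neoplasm plus
others). The six families' base scores occupy disjoint ascending bands
(8–256, 264–520, 584–1024, 1088–1792) with gaps wide enough that
empirical mortality adjustment cannot reorder a populous profile across
a family boundary; with all 24 profiles observed, the distinct-profile
quartiles land exactly between families, so the pipeline recovers
planted levels exactly at detection probability 1 ("oracle closure").
Multi-category profiles outside family IV carry deliberately small
shares (0.015–0.05% each) so the planted multimorbidity share stays
near 16%; at n = 50,000 every profile is comfortably populated, while
runs below ~20,000 subjects may drop a rare profile and shift a
quartile boundary across another rare profile — a sub-0.05-percentage-
point effect on shares, but the reason oracle closure is asserted at
the calibration scale.

Year-to-year dynamics: each chronic subject draws a trajectory —
stable (full profile both years), grow (a planted sub-profile in year
1), shrink (sub-profile or nothing in year 2), or onset (chronic
evidence only in year 2, with 0/1/2 pre-chronic ordinary admissions in
year 1). Every sub-profile ("antecedent") is itself a planted profile,
keeping the distinct-profile universe closed. Mortality is
profile-family-conditional Bernoulli via the terminal share and origin
mix; death dates are uniform over days 60–364 of the death year, and
all of the subject's dated events in the death year precede the death
date.

Evidence emission: each active category-year emits prescriptions under
the rule's ATC prefix with the per-category detection probability
(default 1.0 — categories whose rule has no ATC channel use their
outpatient branch as the guaranteed channel instead), plus redundant
outpatient-branch visits, register rows (cardiovascular/diabetes) and,
for categories certified in both years of a surviving subject,
exemption codes — durable entitlements, hence never emitted for
single-year conditions. Chronic subjects' hospital admissions carry
diagnoses drawn from their active categories; all pre-chronic and
acute-death admissions carry injury-range codes (ICD-9-CM 800–959)
that match no rule. Costs are per-year lognormal budgets with
level-ordered medians (drugs strictly increasing from Healthy through
level IV; hospitalization non-monotone with level II above level III),
split across the year's events; only the ordinal relations are treated
as meaningful.

What the generator does **not** emulate: realistic ICD-9/ATC code
frequency distributions (one representative code per rule channel),
seasonality, within-family correlation of utilization and costs, age-
and sex-specific disease incidence (age is a coarse six-class mixture
per level, loosely older toward higher complexity), migration, or any
re-identification risk structure. Passing tests therefore demonstrate
that the pipeline recovers structure faithfully from well-formed
evidence, not that the default rule table is clinically exhaustive on
real flows.

## Problem sizes and determinism

The calibration scale is n = 50,000 subjects (binomial Monte-Carlo
error < 0.5 pp on every planted share); the test suite uses one shared
50,000-subject run for acceptance-level checks and 300–2,000-subject
runs for structural tests. All randomness derives from a single
integer seed; subjects are seeded independently (`seed:index`), so a
run's first k subjects coincide with a k-subject run and outputs are
byte-identical across repetitions.

## Known limitations

* `admission_type` and `area_of_care` are consumed as given input
  fields; deriving them from DRG/ward codes is out of scope.
* Identifier linkage is exact; probabilistic record linkage is out of
  scope.
* The single-year Early-symptoms / First-diagnostic generalization
  (1 vs ≥2 admissions) is this package's convention; year-over-year
  results for those two levels depend on it.
* Age analytics are produced but uncalibrated; no age standardization
  or significance testing of area differences is provided.
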