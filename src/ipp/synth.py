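"""Synthetic two-year, two-area administrative flows with planted truth.

The generator emulates the eight linked flows of an Italian-NHS-style
population over a two-year window.  Its defaults are calibrated to the
published structure of the cohort the stratification model was developed
on: 39.6% of the population carries a chronic profile (22.2 / 5.1 / 5.3
/ 5.9% across chronicity levels I-IV plus 1.1% terminal), 48% of
terminal patients originate from level IV, chronic subjects keep their
level year-over-year about 84% of the time, and about 40% of
pre-chronic (early-symptoms / first-diagnostic) subjects worsen into
chronicity in the second year.

Profiles are planted at the profile-family level rather than as
independent per-category draws: each chronicity level is represented by
six distinct category combinations whose severity scores occupy
disjoint, strictly ordered bands, so that the quartile stratification of
the full pipeline recovers the planted levels exactly when every
evidence channel fires (detection probability 1, the default).  Planted
evidence is emitted as raw events — prescriptions with the rule's ATC
prefix, outpatient visits in the rule's branch, discharge diagnoses
inside the rule's ICD-9 range, register rows, exemption codes — never as
labels; the ground-truth table exists only as a test oracle.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import pandas as pd
import yaml

from .admin_records import (
    DeathRecord,
    DrugPrescription,
    ERAccess,
    FLOW_KINDS,
    HospitalDischarge,
    ObservationWindow,
    OutpatientRecord,
    RegisterRecord,
    SubjectRegistryRecord,
    write_flow,
)
from .classifier import RuleSet, default_ruleset
from .stratifier import Level

__all__ = [
    "GeneratorConfig",
    "default_config",
    "generate_population",
    "summarize_ground_truth",
    "GROUND_TRUTH_COLUMNS",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# Planted distinct chronic profiles, six per chronicity-level family.
# Severity scores (binary weights) are strictly ordered across families:
# family 1 spans 8-256, family 2 264-520, family 3 584-1024, family 4
# 1088-1792, so distinct-profile quartiles separate the families.
# ``weight`` is the population share in percent; ``antecedent`` is the
# planted sub-profile a subject may hold the year before progressing to
# (or after regressing from) the full profile.
_DEFAULT_PROFILES: list[dict] = [
    # family 1 — single mild chronic category, or COPD+gastro
    {"categories": ["endocrine_metabolic"], "family": 1, "weight": 4.43, "antecedent": None},
    {"categories": ["neuropathy"], "family": 1, "weight": 4.43, "antecedent": None},
    {"categories": ["gastro_enteropathy"], "family": 1, "weight": 4.43, "antecedent": None},
    {"categories": ["copd"], "family": 1, "weight": 4.43, "antecedent": None},
    {"categories": ["cardiovascular"], "family": 1, "weight": 4.43, "antecedent": None},
    {"categories": ["copd", "gastro_enteropathy"], "family": 1, "weight": 0.05,
     "antecedent": ["copd"]},
    # family 2 — cardiovascular plus one comorbidity, or diabetes
    {"categories": ["cardiovascular", "endocrine_metabolic"], "family": 2, "weight": 0.02,
     "antecedent": ["cardiovascular"]},
    {"categories": ["cardiovascular", "neuropathy"], "family": 2, "weight": 0.02,
     "antecedent": ["cardiovascular"]},
    {"categories": ["cardiovascular", "gastro_enteropathy"], "family": 2, "weight": 0.02,
     "antecedent": ["cardiovascular"]},
    {"categories": ["cardiovascular", "copd"], "family": 2, "weight": 0.02,
     "antecedent": ["cardiovascular"]},
    {"categories": ["diabetes"], "family": 2, "weight": 5.00, "antecedent": None},
    {"categories": ["diabetes", "endocrine_metabolic"], "family": 2, "weight": 0.02,
     "antecedent": ["endocrine_metabolic"]},
    # family 3 — more than two categories (no neoplasm), or neoplasm alone
    {"categories": ["diabetes", "gastro_enteropathy", "endocrine_metabolic"], "family": 3,
     "weight": 0.015, "antecedent": ["diabetes", "endocrine_metabolic"]},
    {"categories": ["diabetes", "copd", "gastro_enteropathy"], "family": 3,
     "weight": 0.015, "antecedent": ["diabetes"]},
    {"categories": ["diabetes", "cardiovascular", "endocrine_metabolic"], "family": 3,
     "weight": 0.015, "antecedent": ["cardiovascular", "endocrine_metabolic"]},
    {"categories": ["diabetes", "cardiovascular", "gastro_enteropathy"], "family": 3,
     "weight": 0.015, "antecedent": ["cardiovascular", "gastro_enteropathy"]},
    {"categories": ["diabetes", "cardiovascular", "copd"], "family": 3,
     "weight": 0.015, "antecedent": ["cardiovascular", "copd"]},
    {"categories": ["neoplasm"], "family": 3, "weight": 5.225, "antecedent": None},
    # family 4 — neoplasm combined with other categories
    {"categories": ["neoplasm", "gastro_enteropathy"], "family": 4, "weight": 1.3,
     "antecedent": ["neoplasm"]},
    {"categories": ["neoplasm", "copd"], "family": 4, "weight": 0.9,
     "antecedent": ["neoplasm"]},
    {"categories": ["neoplasm", "cardiovascular"], "family": 4, "weight": 1.4,
     "antecedent": ["neoplasm"]},
    {"categories": ["neoplasm", "cardiovascular", "gastro_enteropathy"], "family": 4,
     "weight": 0.8, "antecedent": ["neoplasm"]},
    {"categories": ["neoplasm", "diabetes"], "family": 4, "weight": 0.9,
     "antecedent": ["neoplasm"]},
    {"categories": ["neoplasm", "diabetes", "cardiovascular"], "family": 4, "weight": 0.6,
     "antecedent": ["neoplasm"]},
]

# Year-to-year trajectory of a surviving chronic subject.  "stable": full
# profile both years; "grow": antecedent in year 1; "shrink": antecedent
# (or nothing) in year 2; "onset_*": chronic evidence only in year 2, with
# 0 / 1 / 2 pre-chronic ordinary admissions in year 1.  Profiles without
# an antecedent cannot grow; their mass sits on stable/shrink/onset.
_TRAJ_NO_ANTE = {"stable": 0.66, "grow": 0.0, "shrink": 0.10,
                 "onset_no": 0.158, "onset_one": 0.064, "onset_two": 0.018}
_TRAJ_ANTE = {"stable": 0.60, "grow": 0.16, "shrink": 0.07,
              "onset_no": 0.10, "onset_one": 0.053, "onset_two": 0.017}

_LEVEL_SHARES = {
    "chronic_i": 22.2,
    "chronic_ii": 5.1,
    "chronic_iii": 5.3,
    "chronic_iv": 5.9,
    "terminal": 1.1,
    "early_symptoms": 6.0,
    "first_diagnostic": 1.5,
    "death_acute": 0.15,
    "pregnancy": 1.5,
    "other_residual": 2.0,
}

# printed 6/26/21/48 sums to 101 (rounding); normalized proportionally
_TERMINAL_ORIGIN = {"chronic_i": 6 / 101, "chronic_ii": 26 / 101,
                    "chronic_iii": 21 / 101, "chronic_iv": 48 / 101}

# per-year utilization by that year's planted level
_UTILIZATION = {
    "healthy": {"ordinary_prob": 0.0, "extra_lambda": 0.0, "daycase_prob": 0.04,
                "surgical_share": 0.295, "unplanned_surgical": 0.74,
                "unplanned_medical": 0.956, "er_prob": 0.04},
    "death_acute": {"ordinary_prob": 0.7, "extra_lambda": 0.0, "daycase_prob": 0.05,
                    "surgical_share": 0.30, "unplanned_surgical": 0.667,
                    "unplanned_medical": 1.0, "er_prob": 0.30},
    "early_symptoms": {"ordinary_prob": 0.0, "extra_lambda": 0.0, "daycase_prob": 0.10,
                       "surgical_share": 0.759, "unplanned_surgical": 0.276,
                       "unplanned_medical": 0.641, "er_prob": 0.12},
    "first_diagnostic": {"ordinary_prob": 0.0, "extra_lambda": 0.0, "daycase_prob": 0.10,
                         "surgical_share": 0.636, "unplanned_surgical": 0.338,
                         "unplanned_medical": 0.718, "er_prob": 0.24},
    "chronic_i": {"ordinary_prob": 0.12, "extra_lambda": 0.3, "daycase_prob": 0.10,
                  "surgical_share": 0.674, "unplanned_surgical": 0.304,
                  "unplanned_medical": 0.729, "er_prob": 0.065},
    "chronic_ii": {"ordinary_prob": 0.20, "extra_lambda": 0.3, "daycase_prob": 0.15,
                   "surgical_share": 0.455, "unplanned_surgical": 0.399,
                   "unplanned_medical": 0.742, "er_prob": 0.10},
    "chronic_iii": {"ordinary_prob": 0.16, "extra_lambda": 0.3, "daycase_prob": 0.15,
                    "surgical_share": 0.514, "unplanned_surgical": 0.411,
                    "unplanned_medical": 0.619, "er_prob": 0.14},
    "chronic_iv": {"ordinary_prob": 0.40, "extra_lambda": 0.3, "daycase_prob": 0.30,
                   "surgical_share": 0.298, "unplanned_surgical": 0.358,
                   "unplanned_medical": 0.576, "er_prob": 0.20},
    "terminal": {"ordinary_prob": 0.50, "extra_lambda": 0.5, "daycase_prob": 0.20,
                 "surgical_share": 0.144, "unplanned_surgical": 0.813,
                 "unplanned_medical": 0.793, "er_prob": 0.45},
}

# annual spending medians (EUR); lognormal, level-ordered
_COSTS = {
    "healthy": {"drug_budget": 60.0, "outpatient_budget": 80.0, "admission_cost": 900.0},
    "death_acute": {"drug_budget": 90.0, "outpatient_budget": 100.0, "admission_cost": 2500.0},
    "early_symptoms": {"drug_budget": 110.0, "outpatient_budget": 150.0, "admission_cost": 1800.0},
    "first_diagnostic": {"drug_budget": 160.0, "outpatient_budget": 450.0, "admission_cost": 1500.0},
    "chronic_i": {"drug_budget": 320.0, "outpatient_budget": 250.0, "admission_cost": 2200.0},
    "chronic_ii": {"drug_budget": 520.0, "outpatient_budget": 350.0, "admission_cost": 3800.0},
    "chronic_iii": {"drug_budget": 800.0, "outpatient_budget": 420.0, "admission_cost": 2600.0},
    "chronic_iv": {"drug_budget": 1300.0, "outpatient_budget": 600.0, "admission_cost": 3500.0},
    "terminal": {"drug_budget": 1600.0, "outpatient_budget": 700.0, "admission_cost": 4500.0},
}

_HOME_CARE = {
    "Area1": {"healthy": 0.002, "death_acute": 0.02, "early_symptoms": 0.004,
              "first_diagnostic": 0.01, "chronic_i": 0.02, "chronic_ii": 0.05,
              "chronic_iii": 0.09, "chronic_iv": 0.16, "terminal": 0.35},
    "Area2": {"healthy": 0.010, "death_acute": 0.02, "early_symptoms": 0.030,
              "first_diagnostic": 0.05, "chronic_i": 0.015, "chronic_ii": 0.04,
              "chronic_iii": 0.07, "chronic_iv": 0.12, "terminal": 0.28},
}

_AGE_CLASSES = [(0, 14), (15, 34), (35, 54), (55, 64), (65, 74), (75, 94)]
_AGE_WEIGHTS = {
    "healthy": [0.18, 0.28, 0.30, 0.12, 0.08, 0.04],
    "death_acute": [0.02, 0.08, 0.15, 0.15, 0.25, 0.35],
    "early_symptoms": [0.10, 0.30, 0.35, 0.12, 0.08, 0.05],
    "first_diagnostic": [0.08, 0.25, 0.35, 0.15, 0.10, 0.07],
    "chronic_i": [0.02, 0.10, 0.30, 0.20, 0.25, 0.13],
    "chronic_ii": [0.01, 0.05, 0.20, 0.22, 0.30, 0.22],
    "chronic_iii": [0.01, 0.04, 0.18, 0.22, 0.30, 0.25],
    "chronic_iv": [0.005, 0.03, 0.15, 0.22, 0.32, 0.275],
    "terminal": [0.005, 0.02, 0.08, 0.15, 0.30, 0.445],
}


@dataclass
class GeneratorConfig:
    """All dials of the synthetic population, YAML round-trippable."""

    n_subjects: int = 50_000
    first_year: int = 2013
    last_year: int = 2014
    # 138,859-resident two-area cohort split (80,641 / 58,218)
    area_shares: dict = field(default_factory=lambda: {"Area1": 0.5808, "Area2": 0.4192})
    female_share: float = 0.51
    level_shares: dict = field(default_factory=lambda: dict(_LEVEL_SHARES))
    terminal_origin: dict = field(default_factory=lambda: dict(_TERMINAL_ORIGIN))
    profiles: list = field(default_factory=lambda: [dict(p) for p in _DEFAULT_PROFILES])
    trajectory_no_antecedent: dict = field(default_factory=lambda: dict(_TRAJ_NO_ANTE))
    trajectory_antecedent: dict = field(default_factory=lambda: dict(_TRAJ_ANTE))
    # probability that a planted category emits its primary (drug) channel
    detection: dict = field(default_factory=dict)  # category -> prob, default 1.0
    outpatient_channel_prob: float = 0.7
    register_channel_prob: float = 0.5
    exemption_channel_prob: float = 0.25
    utilization: dict = field(default_factory=lambda: {k: dict(v) for k, v in _UTILIZATION.items()})
    terminal_death_year: dict = field(default_factory=lambda: {"prob": 0.95, "extra_lambda": 3.5})
    costs: dict = field(default_factory=lambda: {k: dict(v) for k, v in _COSTS.items()})
    drug_sigma: float = 0.5
    outpatient_sigma: float = 0.5
    admission_sigma: float = 0.4
    daycase_cost_factor: float = 0.35
    home_care: dict = field(default_factory=lambda: {a: dict(v) for a, v in _HOME_CARE.items()})
    age_weights: dict = field(default_factory=lambda: {k: list(v) for k, v in _AGE_WEIGHTS.items()})

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        total = sum(self.level_shares.values())
        if total > 100.0 + 1e-9:
            raise ValueError(f"level shares sum to {total} > 100%")
        for p in (self.female_share, self.outpatient_channel_prob,
                  self.register_channel_prob, self.exemption_channel_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for prof in self.profiles:
            if prof["weight"] < 0:
                raise ValueError("profile weights must be non-negative")
            if prof["family"] not in (1, 2, 3, 4):
                raise ValueError("profile family must be 1..4")
        for name, table in (("trajectory_no_antecedent", self.trajectory_no_antecedent),
                            ("trajectory_antecedent", self.trajectory_antecedent)):
            if abs(sum(table.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities must sum to 1")
        fam_weight = {f: 0.0 for f in (1, 2, 3, 4)}
        for prof in self.profiles:
            fam_weight[prof["family"]] += prof["weight"]
        for fam, key in ((1, "chronic_i"), (2, "chronic_ii"), (3, "chronic_iii"), (4, "chronic_iv")):
            if fam_weight[fam] <= 0 and self.level_shares.get(key, 0) > 0:
                raise ValueError(f"no profiles defined for family {fam}")

    @property
    def window(self) -> ObservationWindow:
        return ObservationWindow(self.first_year, self.last_year)

    # -- persistence --------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**doc)


def default_config(n_subjects: int = 50_000) -> GeneratorConfig:
    cfg = GeneratorConfig(n_subjects=n_subjects)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Evidence code book (derived from the rule table)
# ---------------------------------------------------------------------------


class _CodeBook:
    """Concrete event codes satisfying each rule's channels."""

    def __init__(self, rules: RuleSet):
        self.atc: dict[str, str] = {}
        self.branch: dict[str, str] = {}
        self.icd9: dict[str, str] = {}
        self.exemption: dict[str, str] = {}
        for rule in rules:
            if rule.atc_prefixes:
                self.atc[rule.category] = rule.atc_prefixes[0] + "01"
            if rule.outpatient_branches:
                self.branch[rule.category] = rule.outpatient_branches[0]
            for spec in rule.icd9_ranges:
                lo, sep, hi = spec.partition("-")
                if sep and lo.isdigit():
                    self.icd9[rule.category] = lo + "0"
                    break
            else:
                if rule.icd9_ranges:
                    self.icd9[rule.category] = rule.icd9_ranges[0] + "0"
            if rule.exemption_codes:
                self.exemption[rule.category] = rule.exemption_codes[0]


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _weighted_choice(rng: random.Random, items: list, weights: list[float]):
    total = sum(weights)
    u = rng.random() * total
    acc = 0.0
    for item, w in zip(items, weights):
        acc += w
        if u <= acc:
            return item
    return items[-1]


def _day_in_year(rng: random.Random, year: int, max_day: int | None = None) -> date:
    top = 364 if max_day is None else max_day
    return date(year, 1, 1) + timedelta(days=rng.randrange(top + 1))


_LEVEL_KEY = {
    Level.HEALTHY: "healthy",
    Level.DEATH_ACUTE: "death_acute",
    Level.EARLY_SYMPTOMS: "early_symptoms",
    Level.FIRST_DIAGNOSTIC: "first_diagnostic",
    Level.CHRONIC_I: "chronic_i",
    Level.CHRONIC_II: "chronic_ii",
    Level.CHRONIC_III: "chronic_iii",
    Level.CHRONIC_IV: "chronic_iv",
    Level.TERMINAL: "terminal",
}
_FAMILY_LEVEL = {1: Level.CHRONIC_I, 2: Level.CHRONIC_II,
                 3: Level.CHRONIC_III, 4: Level.CHRONIC_IV}

GROUND_TRUTH_COLUMNS = (
    "subject_id", "area", "sex", "birth_year", "categories", "combined_level",
    "origin_level", "died", "death_year", "level_y1", "level_y2", "trajectory",
)


@dataclass
class _Flows:
    registry: list = field(default_factory=list)
    discharges: list = field(default_factory=list)
    drugs: list = field(default_factory=list)
    outpatient: list = field(default_factory=list)
    deaths: list = field(default_factory=list)
    er: list = field(default_factory=list)
    pathology_registers: list = field(default_factory=list)
    home_care_registers: list = field(default_factory=list)

    def as_dict(self) -> dict[str, list]:
        return {k: getattr(self, k) for k in FLOW_KINDS}


def _injury_code(rng: random.Random) -> str:
    # 800-959: injury codes, outside every default rule range
    return f"{rng.randrange(800, 960)}{rng.randrange(10)}"


class _SubjectGenerator:
    def __init__(self, cfg: GeneratorConfig, rules: RuleSet):
        self.cfg = cfg
        self.book = _CodeBook(rules)
        self.y1 = cfg.first_year
        self.y2 = cfg.last_year
        areas = list(cfg.area_shares)
        self.areas = areas
        self.area_weights = [cfg.area_shares[a] for a in areas]
        self.states = list(cfg.level_shares)
        self.state_weights = [cfg.level_shares[s] for s in self.states]
        self.healthy_weight = max(0.0, 100.0 - sum(self.state_weights))
        self.fam_profiles: dict[int, list[dict]] = {f: [] for f in (1, 2, 3, 4)}
        for prof in cfg.profiles:
            self.fam_profiles[prof["family"]].append(prof)
        self.profile_family = {tuple(sorted(p["categories"])): p["family"] for p in cfg.profiles}

    # -- draws --------------------------------------------------------------

    def _draw_state(self, rng: random.Random) -> str:
        return _weighted_choice(rng, self.states + ["healthy"],
                                self.state_weights + [self.healthy_weight])

    def _draw_profile(self, rng: random.Random, family: int) -> dict:
        profs = self.fam_profiles[family]
        return _weighted_choice(rng, profs, [p["weight"] for p in profs])

    def _draw_age(self, rng: random.Random, key: str) -> int:
        lo, hi = _weighted_choice(rng, _AGE_CLASSES, self.cfg.age_weights[key])
        return rng.randrange(lo, hi + 1)

    def _family_level(self, categories: tuple[str, ...]) -> Level:
        return _FAMILY_LEVEL[self.profile_family[tuple(sorted(categories))]]

    # -- event emission -----------------------------------------------------

    def _emit_admission(self, flows: _Flows, rng: random.Random, sid: str, year: int,
                        key: str, diagnoses: list[str], regime: str,
                        max_day: int | None, is_birth: bool = False) -> None:
        u = self.cfg.utilization[key]
        adm = _day_in_year(rng, year, max_day)
        if regime == "ordinary":
            los = 1 + _poisson(rng, 5.0)
        else:
            los = 0
        surgical = rng.random() < u["surgical_share"]
        area_of_care = "surgical" if surgical else "medical"
        p_unplanned = u["unplanned_surgical"] if surgical else u["unplanned_medical"]
        admission_type = "unplanned" if rng.random() < p_unplanned else "planned"
        cost = rng.lognormvariate(math.log(self.cfg.costs[key]["admission_cost"]),
                                  self.cfg.admission_sigma)
        if regime != "ordinary":
            cost *= self.cfg.daycase_cost_factor
            area_of_care = "surgical" if regime == "day_surgery" else "medical"
        if is_birth:
            area_of_care = "medical"
            admission_type = "unplanned" if rng.random() < 0.9 else "planned"
        flows.discharges.append(HospitalDischarge(
            subject_id=sid, admission_date=adm, discharge_date=adm + timedelta(days=los),
            regime=regime, admission_type=admission_type, area_of_care=area_of_care,
            diagnoses=diagnoses, is_birth_event=is_birth, cost=round(cost, 2)))

    def _emit_year(self, flows: _Flows, rng: random.Random, sid: str, year: int,
                   year_level: Level, active: tuple[str, ...],
                   n_prechronic_adm: int, death_day: int | None) -> None:
        """All dated events of one subject-year."""
        cfg = self.cfg
        key = _LEVEL_KEY[year_level]
        u = cfg.utilization[key]
        max_day = death_day

        # --- chronic category evidence (dated channels) ---
        rx_dates: list[date] = []
        rx_codes: list[str] = []
        year_visits: list[OutpatientRecord] = []
        for cat in active:
            # primary (detection-guaranteed) channel: drugs where the rule
            # has an ATC class, otherwise the outpatient branch
            detected = rng.random() < cfg.detection.get(cat, 1.0)
            if cat in self.book.atc:
                if detected:
                    for _ in range(1 + _poisson(rng, 1.2)):
                        rx_dates.append(_day_in_year(rng, year, max_day))
                        rx_codes.append(self.book.atc[cat])
                branch_p = cfg.outpatient_channel_prob
            else:
                branch_p = 1.0 if detected else 0.0
            if cat in self.book.branch and rng.random() < branch_p:
                year_visits.append(OutpatientRecord(
                    sid, _day_in_year(rng, year, max_day), self.book.branch[cat], 0.0))
            register = {"cardiovascular": "heart_failure", "diabetes": "diabetes"}.get(cat)
            if register and rng.random() < cfg.register_channel_prob:
                flows.pathology_registers.append(RegisterRecord(sid, register, year))

        # --- non-chronic pharmacy (OTC-style) ---
        if not active:
            p_otc = 1.0 if key in ("early_symptoms", "first_diagnostic") else 0.5
            if rng.random() < p_otc:
                for _ in range(1 + _poisson(rng, 0.5)):
                    rx_dates.append(_day_in_year(rng, year, max_day))
                    rx_codes.append("N02B01")

        if rx_dates:
            budget = rng.lognormvariate(math.log(cfg.costs[key]["drug_budget"]), cfg.drug_sigma)
            each = round(budget / len(rx_dates), 2)
            for d, code in zip(rx_dates, rx_codes):
                flows.drugs.append(DrugPrescription(sid, d, code, each))

        # --- general outpatient + visit costs ---
        if rng.random() < 0.7:
            year_visits.append(OutpatientRecord(
                sid, _day_in_year(rng, year, max_day), "general_medicine", 0.0))
        if year_visits:
            budget = rng.lognormvariate(math.log(cfg.costs[key]["outpatient_budget"]),
                                        cfg.outpatient_sigma)
            each = round(budget / len(year_visits), 2)
            for r in year_visits:
                r.cost = each
            flows.outpatient.extend(year_visits)

        # --- hospitalizations ---
        def _diagnoses() -> list[str]:
            if active:
                cats = list(active)
                rng.shuffle(cats)
                return [self.book.icd9[c] for c in cats[:2]]
            return [_injury_code(rng)]

        n_ordinary = n_prechronic_adm
        if key in ("chronic_i", "chronic_ii", "chronic_iii", "chronic_iv"):
            if rng.random() < u["ordinary_prob"]:
                n_ordinary += 1 + _poisson(rng, u["extra_lambda"])
        elif key == "terminal":
            if death_day is not None:  # death year: terminal phase
                td = cfg.terminal_death_year
                if rng.random() < td["prob"]:
                    n_ordinary += 1 + _poisson(rng, td["extra_lambda"])
            elif rng.random() < u["ordinary_prob"]:
                n_ordinary += 1 + _poisson(rng, u["extra_lambda"])
        elif key == "death_acute" and death_day is not None:
            if rng.random() < u["ordinary_prob"]:
                n_ordinary += 1
        for _ in range(n_ordinary):
            self._emit_admission(flows, rng, sid, year, key, _diagnoses(),
                                 "ordinary", max_day)
        if rng.random() < u["daycase_prob"]:
            regime = "day_surgery" if rng.random() < 0.5 else "day_hospital"
            self._emit_admission(flows, rng, sid, year, key, _diagnoses(), regime, max_day)

        # --- ER ---
        if rng.random() < u["er_prob"]:
            for _ in range(1 + _poisson(rng, 0.4)):
                flows.er.append(ERAccess(sid, _day_in_year(rng, year, max_day)))

    # -- per-subject --------------------------------------------------------

    def generate_subject(self, idx: int, seed: int, flows: _Flows) -> tuple:
        cfg = self.cfg
        rng = random.Random(f"{seed}:{idx}")
        sid = f"S{idx:07d}"
        area = _weighted_choice(rng, self.areas, self.area_weights)
        state = self._draw_state(rng)
        y1, y2 = self.y1, self.y2

        # resolve planted structure
        active: dict[int, tuple[str, ...]] = {y1: (), y2: ()}
        prechronic: dict[int, int] = {y1: 0, y2: 0}
        died = False
        death_year = 0
        origin: Level | None = None
        trajectory = state
        categories: tuple[str, ...] = ()
        pregnancy_year = 0

        if state in ("chronic_i", "chronic_ii", "chronic_iii", "chronic_iv"):
            family = {"chronic_i": 1, "chronic_ii": 2, "chronic_iii": 3, "chronic_iv": 4}[state]
            prof = self._draw_profile(rng, family)
            full = tuple(prof["categories"])
            ante = tuple(prof["antecedent"]) if prof["antecedent"] else None
            table = cfg.trajectory_antecedent if ante else cfg.trajectory_no_antecedent
            traj = _weighted_choice(rng, list(table), list(table.values()))
            trajectory = traj
            level = _FAMILY_LEVEL[family]
            categories = full
            if traj == "stable":
                active = {y1: full, y2: full}
                year_levels = (level, level)
            elif traj == "grow":
                active = {y1: ante, y2: full}
                year_levels = (self._family_level(ante), level)
            elif traj == "shrink":
                active = {y1: full, y2: ante or ()}
                year_levels = (level, self._family_level(ante) if ante else Level.HEALTHY)
            elif traj == "onset_no":
                active = {y1: (), y2: full}
                year_levels = (Level.HEALTHY, level)
            elif traj == "onset_one":
                active = {y1: (), y2: full}
                prechronic[y1] = 1
                year_levels = (Level.EARLY_SYMPTOMS, level)
            else:  # onset_two
                active = {y1: (), y2: full}
                prechronic[y1] = 2
                year_levels = (Level.FIRST_DIAGNOSTIC, level)
            combined = level
        elif state == "terminal":
            origin_key = _weighted_choice(rng, list(cfg.terminal_origin),
                                          list(cfg.terminal_origin.values()))
            family = {"chronic_i": 1, "chronic_ii": 2, "chronic_iii": 3, "chronic_iv": 4}[origin_key]
            prof = self._draw_profile(rng, family)
            full = tuple(prof["categories"])
            categories = full
            died = True
            death_year = y1 if rng.random() < 0.5 else y2
            origin = _FAMILY_LEVEL[family]
            if death_year == y1:
                active = {y1: full, y2: ()}
                year_levels = (Level.TERMINAL, None)
            else:
                active = {y1: full, y2: full}
                year_levels = (origin, Level.TERMINAL)
            combined = Level.TERMINAL
        elif state == "death_acute":
            died = True
            death_year = y1 if rng.random() < 0.5 else y2
            year_levels = ((Level.DEATH_ACUTE, None) if death_year == y1
                           else (Level.HEALTHY, Level.DEATH_ACUTE))
            combined = Level.DEATH_ACUTE
        elif state == "early_symptoms":
            adm_year = y1 if rng.random() < 0.5 else y2
            prechronic[adm_year] = 1
            year_levels = ((Level.EARLY_SYMPTOMS, Level.HEALTHY) if adm_year == y1
                           else (Level.HEALTHY, Level.EARLY_SYMPTOMS))
            combined = Level.EARLY_SYMPTOMS
        elif state == "first_diagnostic":
            prechronic = {y1: 2, y2: 2}
            year_levels = (Level.FIRST_DIAGNOSTIC, Level.FIRST_DIAGNOSTIC)
            combined = Level.FIRST_DIAGNOSTIC
        elif state == "pregnancy":
            categories = ("pregnancy",)
            pregnancy_year = y1 if rng.random() < 0.5 else y2
            year_levels = (Level.HEALTHY, Level.HEALTHY)
            combined = Level.HEALTHY
        elif state == "other_residual":
            categories = ("other_residual",)
            active = {y1: ("other_residual",), y2: ("other_residual",)}
            year_levels = (Level.HEALTHY, Level.HEALTHY)
            combined = Level.HEALTHY
        else:  # healthy
            year_levels = (Level.HEALTHY, Level.HEALTHY)
            combined = Level.HEALTHY

        # demographics
        age_key = _LEVEL_KEY[combined] if combined != Level.HEALTHY else "healthy"
        if state == "pregnancy":
            sex = "F"
            age = rng.randrange(18, 43)
        else:
            sex = "F" if rng.random() < cfg.female_share else "M"
            age = self._draw_age(rng, age_key)
        birth_year = y1 - age

        # standing exemption codes: categories certified in both years,
        # subjects alive through the window (durable entitlements)
        exemptions: list[str] = []
        if not died:
            for cat in active[y1]:
                if cat in active[y2] and cat in self.book.exemption:
                    if rng.random() < cfg.exemption_channel_prob:
                        exemptions.append(self.book.exemption[cat])

        flows.registry.append(SubjectRegistryRecord(
            sid, birth_year, sex, area, f"GP{rng.randrange(120):03d}", exemptions))

        death_day = None
        if died:
            death_day = rng.randrange(60, 365)
            flows.deaths.append(DeathRecord(sid, date(death_year, 1, 1) + timedelta(days=death_day)))

        # per-year events
        for year, year_level in zip((y1, y2), year_levels):
            if year_level is None:
                continue  # dead before this year
            self._emit_year(flows, rng, sid, year, year_level, active[year],
                            prechronic[year], death_day if died and year == death_year else None)

        # residual-category evidence: non-chronic, undated-channel mix
        if state == "other_residual" and "other_residual" in self.book.exemption:
            if rng.random() < 0.4:
                flows.registry[-1].exemption_codes.append(self.book.exemption["other_residual"])
        if state == "pregnancy":
            self._emit_admission(flows, rng, sid, pregnancy_year, "healthy",
                                 ["650", "V270"], "ordinary", None, is_birth=True)
            flows.outpatient.append(OutpatientRecord(
                sid, _day_in_year(rng, pregnancy_year), "obstetrics", round(rng.uniform(20, 80), 2)))

        # home/community care
        if rng.random() < cfg.home_care[area].get(_LEVEL_KEY[combined], 0.0):
            for year in (y1, y2):
                if not died or year <= death_year:
                    flows.home_care_registers.append(RegisterRecord(sid, "home_care", year))

        lv1, lv2 = year_levels
        return (sid, area, sex, birth_year, "|".join(categories), combined.value,
                origin.value if origin else "", int(died), death_year or "",
                lv1.value, lv2.value if lv2 else "", trajectory)


def generate_population(
    config: GeneratorConfig | None = None,
    seed: int = 42,
    out_dir: str | Path | None = None,
    rules: RuleSet | None = None,
) -> tuple[dict[str, list], pd.DataFrame]:
    """Generate the eight flows plus the ground-truth oracle table.

    Returns ``(flows, ground_truth)``; when ``out_dir`` is given, the
    eight canonical CSVs and ``ground_truth.csv`` are also written
    there.  Same config and seed give byte-identical output; subjects
    are seeded independently, so prefixes of a run coincide with
    smaller runs.
    """
    cfg = config or default_config()
    cfg.validate()
    rules = rules or default_ruleset()
    gen = _SubjectGenerator(cfg, rules)
    flows = _Flows()
    truth_rows = []
    for idx in range(cfg.n_subjects):
        truth_rows.append(gen.generate_subject(idx, seed, flows))
    truth = pd.DataFrame(truth_rows, columns=list(GROUND_TRUTH_COLUMNS))

    flow_dict = flows.as_dict()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for kind, records in flow_dict.items():
            write_flow(records, out_dir / f"{kind}.csv", kind)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return flow_dict, truth


def summarize_ground_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Planted-share report: counts and % of population per planted level.

    Separates generator sampling error from pipeline error in tests.
    """
    if truth.empty:
        return pd.DataFrame(columns=["count", "pct_of_population"])
    counts = truth["combined_level"].value_counts()
    out = pd.DataFrame({
        "count": counts,
        "pct_of_population": 100.0 * counts / len(truth),
    })
    out.index.name = "combined_level"
    return out
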