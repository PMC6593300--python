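"""Step 1 — rule-based classification into pathology macro-categories.

Each subject's linked events are evaluated against one configurable rule
per macro-category.  A rule is an OR over evidence channels (co-pay fee
exemption codes, ICD-9-CM discharge diagnoses, ATC drug prefixes,
outpatient specialty branches, pathology-register flags) and an OR over
events within each channel: a single qualifying in-window event sets the
category flag.  The result is the *patient matrix*: one row per subject,
18 binary columns — the 17 macro-categories in descending order of
severity plus a death flag.  Death never contributes evidence to any
category; it is consumed separately by the second step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .admin_records import EventBundle, ObservationWindow

__all__ = [
    "MacroCategory",
    "CATEGORIES",
    "CATEGORY_NAMES",
    "CHRONIC_CATEGORIES",
    "DEATH_COLUMN",
    "MATRIX_COLUMNS",
    "CategoryRule",
    "RuleSet",
    "default_ruleset",
    "evaluate_rule",
    "build_patient_matrix",
]


@dataclass(frozen=True)
class MacroCategory:
    name: str
    rank: int  # 1 = most severe
    is_chronic: bool


# Fixed severity ordering of the 17 disease macro-categories (rank 1 is the
# most severe).  Pregnancy and the residual class carry no chronic weight.
CATEGORIES: tuple[MacroCategory, ...] = (
    MacroCategory("severe_disability", 1, True),
    MacroCategory("psychiatric_disorders", 2, True),
    MacroCategory("drug_addictions", 3, True),
    MacroCategory("transplants", 4, True),
    MacroCategory("chronic_renal_insufficiency", 5, True),
    MacroCategory("hiv_aids", 6, True),
    MacroCategory("neoplasm", 7, True),
    MacroCategory("diabetes", 8, True),
    MacroCategory("cardiovascular", 9, True),
    MacroCategory("copd", 10, True),
    MacroCategory("gastro_enteropathy", 11, True),
    MacroCategory("neuropathy", 12, True),
    MacroCategory("autoimmune", 13, True),
    MacroCategory("endocrine_metabolic", 14, True),
    MacroCategory("rare_diseases", 15, True),
    MacroCategory("pregnancy", 16, False),
    MacroCategory("other_residual", 17, False),
)

CATEGORY_NAMES: tuple[str, ...] = tuple(c.name for c in CATEGORIES)
CHRONIC_CATEGORIES: frozenset[str] = frozenset(c.name for c in CATEGORIES if c.is_chronic)
CATEGORY_BY_NAME: dict[str, MacroCategory] = {c.name: c for c in CATEGORIES}
DEATH_COLUMN = "death"
MATRIX_COLUMNS: tuple[str, ...] = CATEGORY_NAMES + (DEATH_COLUMN,)


class RuleConfigError(ValueError):
    """The rule table is structurally invalid."""


@dataclass
class CategoryRule:
    """Evidence criteria mapping events to one macro-category.

    ``icd9_ranges`` entries are either ``"LOW-HIGH"`` 3-digit numeric
    ranges matched against the first three characters of a dotless
    ICD-9-CM code, or plain string prefixes (e.g. ``"V42"``).
    """

    category: str
    exemption_codes: list[str] = field(default_factory=list)
    icd9_ranges: list[str] = field(default_factory=list)
    atc_prefixes: list[str] = field(default_factory=list)
    outpatient_branches: list[str] = field(default_factory=list)
    register_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_BY_NAME:
            raise RuleConfigError(f"unknown category {self.category!r}")
        if not any(
            (
                self.exemption_codes,
                self.icd9_ranges,
                self.atc_prefixes,
                self.outpatient_branches,
                self.register_flags,
            )
        ):
            raise RuleConfigError(
                f"rule for {self.category!r} has no evidence channel"
            )
        # precompiled matchers
        numeric: list[tuple[int, int]] = []
        prefixes: list[str] = []
        for spec in self.icd9_ranges:
            lo, sep, hi = spec.partition("-")
            if sep and lo.isdigit() and hi.isdigit():
                numeric.append((int(lo), int(hi)))
            else:
                prefixes.append(spec)
        object.__setattr__(self, "_icd9_numeric", tuple(numeric))
        object.__setattr__(self, "_icd9_prefixes", tuple(prefixes))

    def matches_icd9(self, code: str) -> bool:
        head = code[:3]
        if head.isdigit():
            n = int(head)
            for lo, hi in self._icd9_numeric:  # type: ignore[attr-defined]
                if lo <= n <= hi:
                    return True
        for p in self._icd9_prefixes:  # type: ignore[attr-defined]
            if code.startswith(p):
                return True
        return False

    def matches_atc(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.atc_prefixes)


@dataclass
class RuleSet:
    rules: list[CategoryRule]

    def __post_init__(self) -> None:
        seen = {r.category for r in self.rules}
        if len(seen) != len(self.rules):
            raise RuleConfigError("duplicate rule for a category")

    def __iter__(self):
        return iter(self.rules)

    def __getitem__(self, category: str) -> CategoryRule:
        for r in self.rules:
            if r.category == category:
                return r
        raise KeyError(category)

    def require_complete(self) -> None:
        missing = [c.name for c in CATEGORIES if c.name not in {r.category for r in self.rules}]
        if missing:
            raise RuleConfigError(f"missing rule for categories: {missing}")

    # -- YAML persistence ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "rules": [
                {
                    "category": r.category,
                    "exemption_codes": list(r.exemption_codes),
                    "icd9_ranges": list(r.icd9_ranges),
                    "atc_prefixes": list(r.atc_prefixes),
                    "outpatient_branches": list(r.outpatient_branches),
                    "register_flags": list(r.register_flags),
                }
                for r in self.rules
            ]
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RuleSet":
        text = Path(source).read_text(encoding="utf-8")
        return cls.from_yaml_text(text)

    @classmethod
    def from_yaml_text(cls, text: str) -> "RuleSet":
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict) or "rules" not in doc:
            raise RuleConfigError("rule file must contain a top-level 'rules' list")
        rules = []
        for entry in doc["rules"]:
            try:
                rules.append(CategoryRule(**entry))
            except TypeError as exc:
                raise RuleConfigError(str(exc)) from exc
        return cls(rules)


def default_ruleset() -> RuleSet:
    """The shipped default rule table (17 rules, editable YAML).

    Code lists are a documented, plausible default — the classification
    criteria classes (exemptions, ICD-9-CM diagnoses, ATC drug classes,
    outpatient branches, registers) are fixed; the concrete codes are
    configuration, not algorithm.
    """
    text = resources.files("ipp").joinpath("data/default_rules.yaml").read_text("utf-8")
    return RuleSet.from_yaml_text(text)


def evaluate_rule(
    bundle: EventBundle, rule: CategoryRule, window: ObservationWindow | None = None
) -> bool:
    """True iff any evidence channel matches any in-window event.

    Exemption codes live on the registry record and carry no date; they
    are treated as standing evidence valid for any window.
    """
    window = window or ObservationWindow()
    if rule.exemption_codes:
        codes = set(rule.exemption_codes)
        if any(c in codes for c in bundle.registry.exemption_codes):
            return True
    if rule.icd9_ranges:
        for d in bundle.discharges:
            if window.contains(d.admission_date) and any(
                rule.matches_icd9(code) for code in d.diagnoses
            ):
                return True
    if rule.atc_prefixes:
        for rx in bundle.drugs:
            if window.contains(rx.dispense_date) and rule.matches_atc(rx.atc_code):
                return True
    if rule.outpatient_branches:
        branches = set(rule.outpatient_branches)
        for visit in bundle.outpatient:
            if window.contains(visit.service_date) and visit.branch_code in branches:
                return True
    if rule.register_flags:
        flags = set(rule.register_flags)
        for reg in bundle.registers:
            if reg.register in flags and window.contains_year(reg.year):
                return True
    return False


def build_patient_matrix(
    bundles: dict[str, EventBundle],
    rules: RuleSet,
    window: ObservationWindow | None = None,
) -> pd.DataFrame:
    """Evaluate the full rule table over every bundle.

    Returns the patient matrix: a binary DataFrame indexed by subject_id
    with the 17 category columns in severity-rank order plus ``death``
    (1 iff a death record falls inside the window).
    """
    window = window or ObservationWindow()
    rules.require_complete()
    ordered_rules = [rules[c.name] for c in CATEGORIES]
    data = []
    index = []
    for sid, bundle in bundles.items():
        row = [1 if evaluate_rule(bundle, r, window) else 0 for r in ordered_rules]
        row.append(1 if bundle.died_in(window) else 0)
        data.append(row)
        index.append(sid)
    return pd.DataFrame(data, index=pd.Index(index, name="subject_id"),
                        columns=list(MATRIX_COLUMNS), dtype="int8")


def matrix_to_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path)


def matrix_from_csv(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, index_col="subject_id", dtype={c: "int8" for c in MATRIX_COLUMNS})
    m.index = m.index.astype(str)
    return m
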