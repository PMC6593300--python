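"""Step 2 — profile scoring and assignment of the nine complexity levels.

Each subject's chronic macro-categories form their Individual Profile of
Pathology (IPP).  The profile score is the sum of per-category weights
``w(rank) = 2^(17 - rank)``: binary positional weights make the score a
bijection of the category set, make any single more severe category
outweigh every less severe combination, and therefore order profiles
lexicographically by severity.  Profile scores are then weighted for the
observed proportion of carriers who died (``adj = score * (1 + m)``) and
the quartiles of the distribution of adjusted scores over *distinct*
profiles cut the chronic population into four chronicity levels.

The full level model is a partition into nine states: Healthy, Death for
acute cause, Early symptoms, First diagnostic tests, Chronic I-IV and
Terminal illness (a chronic profile plus in-window death, retaining the
chronic level of origin).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .admin_records import EventBundle, ObservationWindow
from .classifier import (
    CATEGORY_BY_NAME,
    CATEGORY_NAMES,
    CHRONIC_CATEGORIES,
    DEATH_COLUMN,
)

__all__ = [
    "Level",
    "CHRONIC_LEVELS",
    "LevelCutpoints",
    "category_weight",
    "profile_score",
    "matrix_profiles",
    "mortality_adjusted_scores",
    "chronic_level_cutpoints",
    "assign_complexity_level",
    "stratify_population",
    "StratificationResult",
]

N_CATEGORIES = 17


class Level(str, enum.Enum):
    HEALTHY = "Healthy"
    DEATH_ACUTE = "DeathAcute"
    EARLY_SYMPTOMS = "EarlySymptoms"
    FIRST_DIAGNOSTIC = "FirstDiagnostic"
    CHRONIC_I = "ChronicI"
    CHRONIC_II = "ChronicII"
    CHRONIC_III = "ChronicIII"
    CHRONIC_IV = "ChronicIV"
    TERMINAL = "Terminal"

    def __str__(self) -> str:  # plain value in CSV/report output
        return self.value


CHRONIC_LEVELS = (Level.CHRONIC_I, Level.CHRONIC_II, Level.CHRONIC_III, Level.CHRONIC_IV)
LEVEL_ORDER = (
    Level.HEALTHY,
    Level.DEATH_ACUTE,
    Level.EARLY_SYMPTOMS,
    Level.FIRST_DIAGNOSTIC,
    Level.CHRONIC_I,
    Level.CHRONIC_II,
    Level.CHRONIC_III,
    Level.CHRONIC_IV,
    Level.TERMINAL,
)


def category_weight(rank: int, base: int = 2) -> int:
    """Severity weight of a macro-category; strictly decreasing in rank."""
    if not 1 <= rank <= N_CATEGORIES:
        raise ValueError(f"rank must be in 1..{N_CATEGORIES}, got {rank}")
    return base ** (N_CATEGORIES - rank)


def profile_score(categories: Iterable[str]) -> int:
    """Combined IPP score: sum of weights of the profile's categories.

    Only chronic categories may appear in a profile; the empty profile
    scores 0 (not chronic).
    """
    total = 0
    for name in categories:
        cat = CATEGORY_BY_NAME.get(name)
        if cat is None:
            raise ValueError(f"unknown category {name!r}")
        if not cat.is_chronic:
            raise ValueError(f"category {name!r} is not chronic")
        total += category_weight(cat.rank)
    return total


def matrix_profiles(matrix: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Chronic profile (set of chronic categories) of every matrix row."""
    chronic_cols = [c for c in CATEGORY_NAMES if c in CHRONIC_CATEGORIES]
    sub = matrix[chronic_cols].to_numpy(dtype=bool)
    cols = np.array(chronic_cols, dtype=object)
    out: dict[str, frozenset[str]] = {}
    for sid, row in zip(matrix.index, sub):
        out[sid] = frozenset(cols[row]) if row.any() else frozenset()
    return out


@dataclass(frozen=True)
class LevelCutpoints:
    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.q2 <= self.q3):
            raise ValueError("cutpoints must be non-decreasing")

    def chronic_level(self, adjusted_score: float) -> Level:
        # intervals (q_{k-1}, q_k], lowest closed below
        if adjusted_score <= self.q1:
            return Level.CHRONIC_I
        if adjusted_score <= self.q2:
            return Level.CHRONIC_II
        if adjusted_score <= self.q3:
            return Level.CHRONIC_III
        return Level.CHRONIC_IV


def mortality_adjusted_scores(
    profiles: Mapping[str, frozenset[str]],
    died: Mapping[str, bool],
) -> dict[frozenset[str], float]:
    """Adjusted score per distinct non-empty profile.

    ``adj(p) = score(p) * (1 + m(p))`` with ``m(p)`` the proportion of
    carriers of profile ``p`` who died in the window.  The factor is the
    identity at zero mortality and pulls high-mortality profiles upward,
    preserving the severity ordering at equal mortality.
    """
    carriers: dict[frozenset[str], list[bool]] = {}
    for sid, prof in profiles.items():
        if prof:
            carriers.setdefault(prof, []).append(bool(died.get(sid, False)))
    return {
        prof: profile_score(prof) * (1.0 + sum(flags) / len(flags))
        for prof, flags in carriers.items()
    }


def chronic_level_cutpoints(
    adjusted: Mapping[frozenset[str], float] | Iterable[float],
) -> LevelCutpoints:
    """Quartiles (linear interpolation) of the distinct-profile adjusted
    scores, each distinct profile counted once."""
    values = list(adjusted.values()) if isinstance(adjusted, Mapping) else list(adjusted)
    if not values:
        raise ValueError("no chronic profiles: cannot compute cutpoints")
    q1, q2, q3 = np.percentile(np.asarray(values, dtype=float), [25.0, 50.0, 75.0])
    return LevelCutpoints(float(q1), float(q2), float(q3))


def _pre_chronic_level(
    admission_years: Mapping[int, int], window: ObservationWindow
) -> Level:
    """Non-chronic, alive: place by ordinary-hospitalization history.

    Over a multi-year window: admissions in every year -> First
    diagnostic tests; in at least one (but not all) -> Early symptoms.
    Over a single-year window the distinction degenerates, so repeated
    admissions (>=2) stand in for "both years".
    """
    years_with = sum(1 for n in admission_years.values() if n > 0)
    if years_with == 0:
        return Level.HEALTHY
    if window.n_years == 1:
        total = sum(admission_years.values())
        return Level.FIRST_DIAGNOSTIC if total >= 2 else Level.EARLY_SYMPTOMS
    if years_with == window.n_years:
        return Level.FIRST_DIAGNOSTIC
    return Level.EARLY_SYMPTOMS


@dataclass
class ComplexityAssignment:
    subject_id: str
    level: Level
    origin_level: Level | None  # set iff level == Terminal
    score: int
    adjusted_score: float


def assign_complexity_level(
    subject_id: str,
    profile: frozenset[str],
    admission_years: Mapping[int, int],
    died: bool,
    cutpoints: LevelCutpoints | None,
    adjusted: Mapping[frozenset[str], float] | None,
    window: ObservationWindow,
) -> ComplexityAssignment:
    """Assign one of the nine levels by the model's precedence rules."""
    score = profile_score(profile)
    if profile:
        if cutpoints is None or adjusted is None:
            raise ValueError("chronic subject requires cutpoints and adjusted scores")
        adj = adjusted[profile]
        chronic = cutpoints.chronic_level(adj)
        if died:
            return ComplexityAssignment(subject_id, Level.TERMINAL, chronic, score, adj)
        return ComplexityAssignment(subject_id, chronic, None, score, adj)
    if died:
        return ComplexityAssignment(subject_id, Level.DEATH_ACUTE, None, 0, 0.0)
    level = _pre_chronic_level(admission_years, window)
    return ComplexityAssignment(subject_id, level, None, 0, 0.0)


@dataclass
class StratificationResult:
    assignments: pd.DataFrame  # indexed by subject_id
    cutpoints: LevelCutpoints
    summary: pd.DataFrame  # per-level counts, shares, mean categories

    def level_counts(self) -> pd.Series:
        return self.assignments["level"].value_counts()


def stratify_population(
    matrix: pd.DataFrame,
    bundles: Mapping[str, EventBundle],
    window: ObservationWindow | None = None,
) -> StratificationResult:
    """Assign every subject of a classified population a complexity level.

    ``matrix`` is the step-1 patient matrix; ``bundles`` supply the
    hospitalization history for the pre-chronic levels.  Cut-points are
    derived from this same population.
    """
    window = window or ObservationWindow()
    profiles = matrix_profiles(matrix)
    died = {sid: bool(v) for sid, v in matrix[DEATH_COLUMN].items()}
    adjusted = mortality_adjusted_scores(profiles, died)
    cutpoints = chronic_level_cutpoints(adjusted) if adjusted else None

    rows = []
    for sid in matrix.index:
        bundle = bundles[sid]
        a = assign_complexity_level(
            sid,
            profiles[sid],
            bundle.ordinary_admission_years(window),
            died[sid],
            cutpoints,
            adjusted,
            window,
        )
        rows.append(
            (
                a.subject_id,
                window.first_year,
                window.last_year,
                a.level.value,
                a.origin_level.value if a.origin_level else "",
                a.score,
                a.adjusted_score,
            )
        )
    assignments = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "year_start",
            "year_end",
            "level",
            "origin_level",
            "score",
            "adjusted_score",
        ],
    ).set_index("subject_id")

    n_cats = matrix[list(CATEGORY_NAMES)].sum(axis=1)
    levels = assignments["level"]
    summary_rows = []
    n = len(assignments)
    for lv in LEVEL_ORDER:
        mask = levels == lv.value
        cnt = int(mask.sum())
        summary_rows.append(
            {
                "level": lv.value,
                "count": cnt,
                "pct_of_population": 100.0 * cnt / n if n else float("nan"),
                "mean_categories": float(n_cats[mask].mean()) if cnt else float("nan"),
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("level")
    if cutpoints is None:
        cutpoints = LevelCutpoints(0.0, 0.0, 0.0)
    return StratificationResult(assignments, cutpoints, summary)
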