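"""Utilization, spending and progression analytics over a stratified
population.

All functions work from the persisted level assignments plus the raw
flows — no hidden state — and report empty strata as missing (NaN),
never as zero.  Percentage tables are closed compositions: rows and
totals sum to 100 within rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .admin_records import (
    DrugPrescription,
    ERAccess,
    EventBundle,
    HospitalDischarge,
    ObservationWindow,
    OutpatientRecord,
    RegisterRecord,
    SubjectRegistryRecord,
)
from .stratifier import LEVEL_ORDER, Level

__all__ = [
    "hospitalization_rates",
    "demand_breakdown",
    "er_access_prevalence",
    "home_care_rate",
    "spending_by_level",
    "progression_matrix",
    "ProgressionResult",
]

_LEVELS = [lv.value for lv in LEVEL_ORDER]


def _level_of(assignments: pd.DataFrame) -> pd.Series:
    return assignments["level"]


def _qualifying(d: HospitalDischarge, window: ObservationWindow, regime: str | None) -> bool:
    if not window.contains(d.admission_date) or d.is_birth_event:
        return False
    return regime is None or d.regime == regime


def hospitalization_rates(
    assignments: pd.DataFrame,
    discharges: list[HospitalDischarge],
    registry: list[SubjectRegistryRecord],
    window: ObservationWindow | None = None,
    regime: str | None = "ordinary",
) -> pd.DataFrame:
    """Hospitalization rates per 1,000 by level x sex x area.

    Two numerators are reported per stratum: ``rate_subjects`` counts
    subjects with at least one qualifying admission (prevalence-style,
    the primary output) and ``rate_admissions`` counts admissions
    (which can exceed 1,000).  Birth events (deliveries and healthy
    newborns) never qualify.  Empty strata are NaN.
    """
    window = window or ObservationWindow()
    reg = pd.DataFrame(
        {"subject_id": [r.subject_id for r in registry],
         "sex": [r.sex for r in registry],
         "area": [r.area for r in registry]}
    ).set_index("subject_id")
    df = reg.join(assignments[["level"]], how="inner")

    n_adm: dict[str, int] = {}
    for d in discharges:
        if _qualifying(d, window, regime):
            n_adm[d.subject_id] = n_adm.get(d.subject_id, 0) + 1
    df["n_admissions"] = df.index.map(lambda s: n_adm.get(s, 0))
    df["any_admission"] = (df["n_admissions"] > 0).astype(int)

    groups = df.groupby(["level", "sex", "area"], observed=True)
    out = groups.agg(
        population=("any_admission", "size"),
        subjects_hospitalized=("any_admission", "sum"),
        admissions=("n_admissions", "sum"),
    ).reset_index()
    out["rate_subjects"] = 1000.0 * out["subjects_hospitalized"] / out["population"]
    out["rate_admissions"] = 1000.0 * out["admissions"] / out["population"]
    return out


def demand_breakdown(
    assignments: pd.DataFrame,
    discharges: list[HospitalDischarge],
    window: ObservationWindow | None = None,
) -> pd.DataFrame:
    """Overall hospitalization demand by level.

    Demand counts admissions under all three regimes (ordinary, day
    hospital, day surgery), excluding birth events.  Per level:
    percentage of total demand, surgical/medical split, and the
    unplanned share within each area of care.
    """
    window = window or ObservationWindow()
    level = _level_of(assignments)
    rows = []
    for d in discharges:
        if not _qualifying(d, window, None):
            continue
        lv = level.get(d.subject_id)
        if lv is None:
            continue
        rows.append((lv, d.area_of_care, d.admission_type))
    df = pd.DataFrame(rows, columns=["level", "area_of_care", "admission_type"])
    total = len(df)
    out = []
    for lv in _LEVELS:
        sub = df[df["level"] == lv]
        n = len(sub)
        surgical = sub[sub["area_of_care"] == "surgical"]
        medical = sub[sub["area_of_care"] == "medical"]

        def _pct_unplanned(part: pd.DataFrame) -> float:
            if len(part) == 0:
                return float("nan")
            return 100.0 * (part["admission_type"] == "unplanned").mean()

        out.append(
            {
                "level": lv,
                "n_admissions": n,
                "pct_of_total_demand": 100.0 * n / total if total else float("nan"),
                "pct_surgical": 100.0 * len(surgical) / n if n else float("nan"),
                "pct_surgical_unplanned": _pct_unplanned(surgical),
                "pct_medical": 100.0 * len(medical) / n if n else float("nan"),
                "pct_medical_unplanned": _pct_unplanned(medical),
            }
        )
    return pd.DataFrame(out).set_index("level")


def er_access_prevalence(
    assignments: pd.DataFrame,
    er_events: list[ERAccess],
    window: ObservationWindow | None = None,
) -> pd.Series:
    """Percent of each level's population with >= 1 ER access in-window."""
    window = window or ObservationWindow()
    with_access = {e.subject_id for e in er_events if window.contains(e.access_date)}
    level = _level_of(assignments)
    flags = level.index.isin(with_access)
    out = {}
    for lv in _LEVELS:
        mask = (level == lv).to_numpy()
        out[lv] = 100.0 * flags[mask].mean() if mask.any() else float("nan")
    return pd.Series(out, name="pct_with_er_access")


def home_care_rate(
    assignments: pd.DataFrame,
    registers: list[RegisterRecord],
    registry: list[SubjectRegistryRecord],
    window: ObservationWindow | None = None,
) -> pd.DataFrame:
    """Percent of subjects in the home-care register by level and area."""
    window = window or ObservationWindow()
    in_care = {
        r.subject_id
        for r in registers
        if r.register == "home_care" and window.contains_year(r.year)
    }
    area = pd.Series({r.subject_id: r.area for r in registry})
    level = _level_of(assignments)
    df = pd.DataFrame({"level": level, "area": area.reindex(level.index)})
    df["in_care"] = df.index.isin(in_care)
    groups = df.groupby(["level", "area"], observed=True)["in_care"]
    out = groups.agg(population="size", n_in_care="sum").reset_index()
    out["pct_in_home_care"] = 100.0 * out["n_in_care"] / out["population"]
    return out


def spending_by_level(
    assignments: pd.DataFrame,
    drugs: list[DrugPrescription],
    outpatient: list[OutpatientRecord],
    discharges: list[HospitalDischarge],
    window: ObservationWindow | None = None,
) -> pd.DataFrame:
    """Mean annual spending per subject by level and spending stream.

    Means are taken over the whole level population, zero-spenders
    included, and divided by the number of observation years.
    """
    window = window or ObservationWindow()
    years = window.n_years
    level = _level_of(assignments)

    def _totals(events, date_attr: str) -> dict[str, float]:
        acc: dict[str, float] = {}
        for e in events:
            if window.contains(getattr(e, date_attr)):
                acc[e.subject_id] = acc.get(e.subject_id, 0.0) + e.cost
        return acc

    streams = {
        "drugs": _totals(drugs, "dispense_date"),
        "outpatient": _totals(outpatient, "service_date"),
        "hospitalization": _totals(discharges, "admission_date"),
    }
    out = []
    for lv in _LEVELS:
        ids = level.index[level == lv]
        n = len(ids)
        row: dict[str, float | str | int] = {"level": lv, "population": n}
        for name, totals in streams.items():
            if n == 0:
                row[f"mean_{name}"] = float("nan")
            else:
                row[f"mean_{name}"] = sum(totals.get(s, 0.0) for s in ids) / n / years
        out.append(row)
    return pd.DataFrame(out).set_index("level")


@dataclass
class ProgressionResult:
    matrix: pd.DataFrame  # 9x9 row-conditional percentages
    counts: pd.DataFrame  # raw transition counts
    entrants: list[str]  # subjects in year 2 but not year 1
    excluded_deaths: list[str]  # died in year 1, excluded from rows


def progression_matrix(
    assignments_y1: pd.DataFrame,
    assignments_y2: pd.DataFrame,
    deaths_in_y1: set[str] | None = None,
) -> ProgressionResult:
    """Year-over-year complexity progression.

    ``cell(r, c) = 100 * n(level r in year 1 and level c in year 2) /
    n(level r in year 1)`` over subjects present in both years.
    Subjects who died in year 1 have no year-2 state and are excluded;
    subjects appearing only in year 2 are reported as entrants.
    """
    deaths_in_y1 = deaths_in_y1 or set()
    l1 = _level_of(assignments_y1)
    l2 = _level_of(assignments_y2)
    common = l1.index.intersection(l2.index)
    keep = [s for s in common if s not in deaths_in_y1]
    y1_ids = set(l1.index)
    entrants = [s for s in l2.index if s not in y1_ids]
    excluded = [s for s in l1.index if s in deaths_in_y1]

    counts = pd.DataFrame(0, index=_LEVELS, columns=_LEVELS, dtype=int)
    sub1 = l1.loc[keep]
    sub2 = l2.loc[keep]
    tab = pd.crosstab(sub1, sub2)
    for r in tab.index:
        for c in tab.columns:
            counts.loc[r, c] = int(tab.loc[r, c])

    row_totals = counts.sum(axis=1)
    pct = counts.astype(float)
    for r in _LEVELS:
        t = row_totals[r]
        pct.loc[r] = 100.0 * counts.loc[r] / t if t else np.nan
    pct.index.name = "level_year1"
    pct.columns.name = "level_year2"
    return ProgressionResult(pct, counts, entrants, excluded)
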