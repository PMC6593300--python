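"""Canonical data model, CSV readers/writers and subject-level linkage.

Eight administrative flows, keyed by an anonymized subject identifier,
describe a population's contacts with the healthcare system over an
observation window:

* ``registry`` — one row per resident (demographics, GP, co-pay fee
  exemption codes),
* ``discharges`` — hospital discharge forms with all diagnoses,
* ``drugs`` — reimbursed outpatient drug prescriptions (ATC coded),
* ``outpatient`` — outpatient visits / laboratory and imaging tests,
* ``deaths`` — mortality data,
* ``er`` — emergency-room accesses,
* ``pathology_registers`` — GP-reported heart-failure and diabetes
  registers,
* ``home_care_registers`` — subjects receiving home assistance.

The real record layouts of such flows are proprietary, so this module
defines its own stable, headered-CSV schema per flow (UTF-8, ISO-8601
dates, one record type per file) and exact-identifier linkage into
per-subject :class:`EventBundle` objects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ObservationWindow",
    "SubjectRegistryRecord",
    "HospitalDischarge",
    "DrugPrescription",
    "OutpatientRecord",
    "DeathRecord",
    "ERAccess",
    "RegisterRecord",
    "EventBundle",
    "FlowReadResult",
    "LinkResult",
    "FLOW_KINDS",
    "read_flow",
    "write_flow",
    "link_subjects",
]

REGIMES = ("ordinary", "day_hospital", "day_surgery")
ADMISSION_TYPES = ("planned", "unplanned")
AREAS_OF_CARE = ("surgical", "medical")
REGISTERS = ("heart_failure", "diabetes", "home_care")


class SchemaError(ValueError):
    """A flow file does not match its canonical schema."""


@dataclass(frozen=True)
class ObservationWindow:
    """Closed range of calendar years events are evaluated against."""

    first_year: int = 2013
    last_year: int = 2014

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ValueError("last_year must be >= first_year")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.first_year, self.last_year + 1))

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    def contains(self, d: date) -> bool:
        return self.first_year <= d.year <= self.last_year

    def contains_year(self, year: int) -> bool:
        return self.first_year <= year <= self.last_year

    def single_year(self, year: int) -> "ObservationWindow":
        return ObservationWindow(year, year)


@dataclass
class SubjectRegistryRecord:
    subject_id: str
    birth_year: int
    sex: str  # "F" | "M"
    area: str
    gp_id: str = ""
    exemption_codes: list[str] = field(default_factory=list)


@dataclass
class HospitalDischarge:
    subject_id: str
    admission_date: date
    discharge_date: date
    regime: str
    admission_type: str
    area_of_care: str
    diagnoses: list[str]  # ICD-9-CM without dots, principal first
    is_birth_event: bool = False
    cost: float = 0.0


@dataclass
class DrugPrescription:
    subject_id: str
    dispense_date: date
    atc_code: str
    cost: float = 0.0


@dataclass
class OutpatientRecord:
    subject_id: str
    service_date: date
    branch_code: str
    cost: float = 0.0


@dataclass
class DeathRecord:
    subject_id: str
    death_date: date


@dataclass
class ERAccess:
    subject_id: str
    access_date: date


@dataclass
class RegisterRecord:
    subject_id: str
    register: str  # heart_failure | diabetes | home_care
    year: int


@dataclass
class EventBundle:
    """All linked administrative events for one subject."""

    subject_id: str
    registry: SubjectRegistryRecord
    discharges: list[HospitalDischarge] = field(default_factory=list)
    drugs: list[DrugPrescription] = field(default_factory=list)
    outpatient: list[OutpatientRecord] = field(default_factory=list)
    er: list[ERAccess] = field(default_factory=list)
    registers: list[RegisterRecord] = field(default_factory=list)
    death: DeathRecord | None = None

    def n_events(self) -> int:
        return (
            len(self.discharges)
            + len(self.drugs)
            + len(self.outpatient)
            + len(self.er)
            + len(self.registers)
            + (1 if self.death is not None else 0)
        )

    def died_in(self, window: ObservationWindow) -> bool:
        return self.death is not None and window.contains(self.death.death_date)

    def ordinary_admission_years(self, window: ObservationWindow) -> dict[int, int]:
        """Per-year counts of ordinary-regime, non-birth admissions."""
        counts: dict[int, int] = {y: 0 for y in window.years}
        for d in self.discharges:
            if d.regime != "ordinary" or d.is_birth_event:
                continue
            y = d.admission_date.year
            if window.contains_year(y):
                counts[y] += 1
        return counts


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_LIST_SEP = "|"


def _parse_date(s: str) -> date:
    return date.fromisoformat(s)


def _parse_cost(s: str) -> float:
    v = float(s)
    if v < 0:
        raise ValueError("cost must be >= 0")
    return v


def _parse_bool(s: str) -> bool:
    if s in ("true", "True", "1"):
        return True
    if s in ("false", "False", "0", ""):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _parse_list(s: str) -> list[str]:
    return [p for p in s.split(_LIST_SEP) if p] if s else []


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, list):
        return _LIST_SEP.join(value)
    if isinstance(value, float):
        return format(value, ".2f")
    return str(value)


def _choice(options: Sequence[str]):
    def parse(s: str) -> str:
        if s not in options:
            raise ValueError(f"expected one of {options}, got {s!r}")
        return s

    return parse


# flow kind -> (record class, {column: parser})
_SCHEMAS: dict[str, tuple[type, dict[str, object]]] = {
    "registry": (
        SubjectRegistryRecord,
        {
            "subject_id": str,
            "birth_year": int,
            "sex": _choice(("F", "M")),
            "area": str,
            "gp_id": str,
            "exemption_codes": _parse_list,
        },
    ),
    "discharges": (
        HospitalDischarge,
        {
            "subject_id": str,
            "admission_date": _parse_date,
            "discharge_date": _parse_date,
            "regime": _choice(REGIMES),
            "admission_type": _choice(ADMISSION_TYPES),
            "area_of_care": _choice(AREAS_OF_CARE),
            "diagnoses": _parse_list,
            "is_birth_event": _parse_bool,
            "cost": _parse_cost,
        },
    ),
    "drugs": (
        DrugPrescription,
        {
            "subject_id": str,
            "dispense_date": _parse_date,
            "atc_code": str,
            "cost": _parse_cost,
        },
    ),
    "outpatient": (
        OutpatientRecord,
        {
            "subject_id": str,
            "service_date": _parse_date,
            "branch_code": str,
            "cost": _parse_cost,
        },
    ),
    "deaths": (DeathRecord, {"subject_id": str, "death_date": _parse_date}),
    "er": (ERAccess, {"subject_id": str, "access_date": _parse_date}),
    "pathology_registers": (
        RegisterRecord,
        {
            "subject_id": str,
            "register": _choice(("heart_failure", "diabetes")),
            "year": int,
        },
    ),
    "home_care_registers": (
        RegisterRecord,
        {"subject_id": str, "register": _choice(("home_care",)), "year": int},
    ),
}

FLOW_KINDS = tuple(_SCHEMAS)


def _validate_record(kind: str, rec) -> str | None:
    """Return a rejection reason for records violating flow invariants."""
    if kind == "discharges":
        if rec.discharge_date < rec.admission_date:
            return "date order"
        if not rec.diagnoses:
            return "no diagnoses"
    elif kind == "drugs":
        if not rec.atc_code:
            return "empty atc_code"
    elif kind == "registry":
        if not rec.subject_id:
            return "empty subject_id"
    return None


@dataclass
class RejectedRow:
    row_number: int  # 1-based, excluding the header
    reason: str
    raw: dict


@dataclass
class FlowReadResult:
    kind: str
    records: list
    rejects: list[RejectedRow]


def flow_columns(kind: str) -> tuple[str, ...]:
    if kind not in _SCHEMAS:
        raise SchemaError(f"unknown flow kind {kind!r}")
    return tuple(_SCHEMAS[kind][1])


def read_flow(path: str | Path, kind: str) -> FlowReadResult:
    """Parse one canonical CSV flow file into typed records.

    Malformed rows are collected into the rejects report with the reason,
    never silently dropped.  A missing mandatory column is a
    :class:`SchemaError` naming the column.
    """
    if kind not in _SCHEMAS:
        raise SchemaError(f"unknown flow kind {kind!r}")
    cls, colspec = _SCHEMAS[kind]
    records: list = []
    rejects: list[RejectedRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in colspec:
            if col not in header:
                raise SchemaError(f"flow {kind!r}: missing mandatory column {col!r}")
        for i, row in enumerate(reader, start=1):
            try:
                kwargs = {col: parser(row[col]) for col, parser in colspec.items()}  # type: ignore[operator]
                rec = cls(**kwargs)
            except (ValueError, TypeError) as exc:
                rejects.append(RejectedRow(i, str(exc), dict(row)))
                continue
            reason = _validate_record(kind, rec)
            if reason is not None:
                rejects.append(RejectedRow(i, reason, dict(row)))
            else:
                records.append(rec)
    return FlowReadResult(kind, records, rejects)


def write_flow(records: Iterable, path: str | Path, kind: str) -> None:
    """Write typed records to a canonical CSV file (round-trips with
    :func:`read_flow`)."""
    if kind not in _SCHEMAS:
        raise SchemaError(f"unknown flow kind {kind!r}")
    cols = flow_columns(kind)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            writer.writerow([_fmt(getattr(rec, c)) for c in cols])


def read_flow_dir(directory: str | Path) -> dict[str, FlowReadResult]:
    """Read every flow CSV present in ``directory`` (``<kind>.csv``)."""
    directory = Path(directory)
    out: dict[str, FlowReadResult] = {}
    for kind in FLOW_KINDS:
        p = directory / f"{kind}.csv"
        if p.exists():
            out[kind] = read_flow(p, kind)
    return out


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------


@dataclass
class OrphanEvent:
    kind: str
    subject_id: str


@dataclass
class LinkResult:
    bundles: dict[str, EventBundle]
    orphans: list[OrphanEvent]
    n_out_of_window: int

    def total_events(self) -> int:
        return sum(b.n_events() for b in self.bundles.values())


def link_subjects(
    flows: dict[str, list | FlowReadResult],
    window: ObservationWindow | None = None,
) -> LinkResult:
    """Link every flow to its registry subject by exact anonymized ID.

    Returns one :class:`EventBundle` per registry subject.  Events whose
    subject is absent from the registry are reported as orphans.  Events
    dated outside the window are linked but counted in
    ``n_out_of_window`` (downstream classification filters by window).
    """
    window = window or ObservationWindow()

    def records_of(kind: str) -> list:
        v = flows.get(kind, [])
        return v.records if isinstance(v, FlowReadResult) else list(v)

    registry = records_of("registry")
    if not registry:
        raise ValueError("registry flow is empty: nothing to link")

    bundles: dict[str, EventBundle] = {}
    for reg in registry:
        if reg.subject_id in bundles:
            raise ValueError(f"duplicate registry subject_id {reg.subject_id!r}")
        bundles[reg.subject_id] = EventBundle(subject_id=reg.subject_id, registry=reg)

    orphans: list[OrphanEvent] = []
    n_oow = 0

    def _event_date(kind: str, rec) -> date | None:
        if kind == "discharges":
            return rec.admission_date
        if kind == "drugs":
            return rec.dispense_date
        if kind == "outpatient":
            return rec.service_date
        if kind == "deaths":
            return rec.death_date
        if kind == "er":
            return rec.access_date
        return None

    attr = {
        "discharges": "discharges",
        "drugs": "drugs",
        "outpatient": "outpatient",
        "er": "er",
        "pathology_registers": "registers",
        "home_care_registers": "registers",
    }
    for kind in attr:
        for rec in records_of(kind):
            bundle = bundles.get(rec.subject_id)
            if bundle is None:
                orphans.append(OrphanEvent(kind, rec.subject_id))
                continue
            d = _event_date(kind, rec)
            if d is not None and not window.contains(d):
                n_oow += 1
            elif d is None and not window.contains_year(rec.year):
                n_oow += 1
            getattr(bundle, attr[kind]).append(rec)

    for rec in records_of("deaths"):
        bundle = bundles.get(rec.subject_id)
        if bundle is None:
            orphans.append(OrphanEvent("deaths", rec.subject_id))
            continue
        if bundle.death is not None:
            raise ValueError(f"multiple death records for {rec.subject_id!r}")
        if not window.contains(rec.death_date):
            n_oow += 1
        bundle.death = rec

    return LinkResult(bundles=bundles, orphans=orphans, n_out_of_window=n_oow)
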