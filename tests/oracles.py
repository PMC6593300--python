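"""Independent oracles and random-fixture builders for the test suite.

The rule oracle deliberately re-implements category matching in the
most naive way possible — a double loop over every (event, channel)
pair with inline string/range checks — so that it shares no code with
the package's precompiled matchers.
"""

from __future__ import annotations

import random
from datetime import date

from ipp.admin_records import (
    DeathRecord,
    DrugPrescription,
    ERAccess,
    EventBundle,
    HospitalDischarge,
    ObservationWindow,
    OutpatientRecord,
    RegisterRecord,
    SubjectRegistryRecord,
)


def oracle_icd9_match(code: str, spec: str) -> bool:
    lo, sep, hi = spec.partition("-")
    if sep and lo.isdigit() and hi.isdigit():
        head = code[:3]
        return head.isdigit() and int(lo) <= int(head) <= int(hi)
    return code.startswith(spec)


def oracle_evaluate(bundle: EventBundle, rule, window: ObservationWindow) -> bool:
    """Brute-force OR over every event and every channel entry."""
    for code in bundle.registry.exemption_codes:
        for wanted in rule.exemption_codes:
            if code == wanted:
                return True
    for discharge in bundle.discharges:
        if not window.contains(discharge.admission_date):
            continue
        for code in discharge.diagnoses:
            for spec in rule.icd9_ranges:
                if oracle_icd9_match(code, spec):
                    return True
    for rx in bundle.drugs:
        if not window.contains(rx.dispense_date):
            continue
        for prefix in rule.atc_prefixes:
            if rx.atc_code.startswith(prefix):
                return True
    for visit in bundle.outpatient:
        if not window.contains(visit.service_date):
            continue
        for branch in rule.outpatient_branches:
            if visit.branch_code == branch:
                return True
    for reg in bundle.registers:
        if not window.contains_year(reg.year):
            continue
        for flag in rule.register_flags:
            if reg.register == flag:
                return True
    return False


# ---------------------------------------------------------------------------
# random small-bundle factory
# ---------------------------------------------------------------------------

_EXEMPTIONS = ["048", "013", "002", "057", "099", "ZZZ", "044"]
_ICD9 = ["1748", "250", "4280", "4910", "585", "8540", "V270", "V422", "730", "20800"]
_ATC = ["L01XA01", "A10BA02", "C09AA05", "N02BE01", "R03AC02", "H03AA01", "B01AC06"]
_BRANCHES = ["oncology", "cardiology", "general_medicine", "obstetrics", "dialysis"]
_REGISTERS = ["heart_failure", "diabetes", "home_care"]


def random_bundle(rng: random.Random, subject_id: str = "X") -> EventBundle:
    """A small random bundle mixing matching and non-matching evidence,
    with some events dated outside the 2013-2014 window."""

    def _date() -> date:
        return date(rng.choice([2011, 2013, 2014, 2016]), rng.randrange(1, 13),
                    rng.randrange(1, 29))

    registry = SubjectRegistryRecord(
        subject_id, 1950, "F", "Area1", "GP001",
        rng.sample(_EXEMPTIONS, k=rng.randrange(0, 3)))
    bundle = EventBundle(subject_id=subject_id, registry=registry)
    for _ in range(rng.randrange(0, 3)):
        d = _date()
        bundle.discharges.append(HospitalDischarge(
            subject_id, d, d, rng.choice(["ordinary", "day_hospital"]),
            rng.choice(["planned", "unplanned"]),
            rng.choice(["surgical", "medical"]),
            rng.sample(_ICD9, k=rng.randrange(1, 3)),
            rng.random() < 0.1, round(rng.uniform(0, 5000), 2)))
    for _ in range(rng.randrange(0, 3)):
        bundle.drugs.append(DrugPrescription(
            subject_id, _date(), rng.choice(_ATC), round(rng.uniform(0, 100), 2)))
    for _ in range(rng.randrange(0, 3)):
        bundle.outpatient.append(OutpatientRecord(
            subject_id, _date(), rng.choice(_BRANCHES), round(rng.uniform(0, 200), 2)))
    for _ in range(rng.randrange(0, 2)):
        bundle.er.append(ERAccess(subject_id, _date()))
    for _ in range(rng.randrange(0, 2)):
        bundle.registers.append(RegisterRecord(
            subject_id, rng.choice(_REGISTERS), rng.choice([2012, 2013, 2014])))
    if rng.random() < 0.2:
        bundle.death = DeathRecord(subject_id, _date())
    return bundle
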