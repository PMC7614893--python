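"""Domain types for SLE patient-visit data and their CSV readers/writers.

The unit of disease-activity measurement is a classic BILAG assessment:
eight organ domains each graded A (severe activity) through E (never
active).  A :class:`Visit` bundles one assessment time point — BILAG,
SLEDAI-2K, damage index (SDI), therapy, serology, questionnaires — and a
:class:`Patient` holds a time-ordered visit history.  Time is expressed in
months from enrolment; absent values are first-class (``None``), never
sentinel numbers, because registry denominators differ per variable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "Grade",
    "Agent",
    "SmokingStatus",
    "ORGAN_DOMAINS",
    "BILAGAssessment",
    "Visit",
    "Patient",
    "Cohort",
    "CohortError",
    "ParseError",
    "JoinError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
]


class CohortError(Exception):
    """Base class for cohort I/O and validation failures."""


class ParseError(CohortError):
    """A cell could not be parsed; carries the offending file row."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class JoinError(CohortError):
    """visits.csv references a patient_id absent from patients.csv."""


class ValidationError(CohortError):
    """An in-memory object violates a structural invariant."""


class Grade(str, enum.Enum):
    """Classic BILAG organ-domain grade; A and B denote active disease."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"

    @property
    def is_active(self) -> bool:
        return self in (Grade.A, Grade.B)


class Agent(str, enum.Enum):
    """Individual immunosuppressant agents recorded per visit."""

    azathioprine = "azathioprine"
    mycophenolate = "mycophenolate"
    methotrexate = "methotrexate"
    cyclosporine = "cyclosporine"
    cyclophosphamide_iv = "cyclophosphamide_iv"
    cyclophosphamide_oral = "cyclophosphamide_oral"
    other = "other"


class SmokingStatus(str, enum.Enum):
    current = "current"
    previous = "previous"
    never = "never"


ORGAN_DOMAINS: tuple[str, ...] = (
    "constitutional",
    "mucocutaneous",
    "neuropsychiatric",
    "musculoskeletal",
    "cardiorespiratory",
    "vasculitis",
    "renal",
    "haematological",
)

ETHNICITIES = ("Caucasian", "Hispanic", "Asian", "African", "Other")
LOCATIONS = ("Canada", "United States", "Mexico", "Europe", "Asia")

SLEDAI_MAX = 105  # theoretical maximum of the SLEDAI-2K instrument


@dataclass(frozen=True)
class BILAGAssessment:
    """One complete classic BILAG assessment (all 8 domains graded).

    Partial assessments are not representable: a missing assessment is a
    ``None`` at the :class:`Visit` level.
    """

    constitutional: Grade
    mucocutaneous: Grade
    neuropsychiatric: Grade
    musculoskeletal: Grade
    cardiorespiratory: Grade
    vasculitis: Grade
    renal: Grade
    haematological: Grade

    def __post_init__(self):
        for name in ORGAN_DOMAINS:
            g = getattr(self, name)
            if not isinstance(g, Grade):
                raise ValidationError(f"domain {name!r}: not a Grade: {g!r}")

    def grade(self, domain: str) -> Grade:
        return getattr(self, domain)

    def grades(self) -> tuple[Grade, ...]:
        return tuple(getattr(self, d) for d in ORGAN_DOMAINS)

    def active_domains(self) -> tuple[str, ...]:
        """Domains currently graded A or B."""
        return tuple(d for d in ORGAN_DOMAINS if self.grade(d).is_active)

    @classmethod
    def from_mapping(cls, grades: Mapping[str, str | Grade]) -> "BILAGAssessment":
        return cls(**{d: Grade(grades[d]) for d in ORGAN_DOMAINS})


@dataclass(frozen=True)
class Visit:
    """A single assessment time point for one patient.

    ``oral_steroid_dose`` is the average daily oral prednisolone-equivalent
    dose in mg/day; a recorded 0 means "not on oral steroids", ``None``
    means unrecorded.  ``agents`` lists individual immunosuppressants and
    must be consistent with ``immunosuppressant_any``.
    """

    patient_id: str
    months_from_enrolment: float
    bilag: Optional[BILAGAssessment] = None
    sledai_2k: Optional[int] = None
    sdi: Optional[int] = None
    oral_steroid_dose: Optional[float] = None
    pulse_steroid: bool = False
    antimalarial: bool = False
    immunosuppressant_any: bool = False
    agents: frozenset[Agent] = frozenset()
    biologic_any: bool = False
    low_complement: Optional[bool] = None
    high_dsdna: Optional[bool] = None
    acl: Optional[bool] = None
    anti_b2gp1: Optional[bool] = None
    lupus_anticoagulant: Optional[bool] = None
    sf36_pcs: Optional[float] = None
    sf36_mcs: Optional[float] = None
    hypertension: Optional[bool] = None
    diabetes: Optional[bool] = None
    smoking_status: Optional[SmokingStatus] = None
    alcohol_units_per_week: Optional[float] = None

    def __post_init__(self):
        if self.months_from_enrolment < 0:
            raise ValidationError(
                f"{self.patient_id}: negative months_from_enrolment"
            )
        if self.agents and not self.immunosuppressant_any:
            raise ValidationError(
                f"{self.patient_id}: agents non-empty but immunosuppressant_any false"
            )
        if self.sledai_2k is not None and not 0 <= self.sledai_2k <= SLEDAI_MAX:
            raise ValidationError(
                f"{self.patient_id}: sledai_2k {self.sledai_2k} outside [0, {SLEDAI_MAX}]"
            )
        if self.sdi is not None and self.sdi < 0:
            raise ValidationError(f"{self.patient_id}: negative sdi")
        if self.oral_steroid_dose is not None and self.oral_steroid_dose < 0:
            raise ValidationError(f"{self.patient_id}: negative oral_steroid_dose")
        if (
            self.alcohol_units_per_week is not None
            and self.alcohol_units_per_week < 0
        ):
            raise ValidationError(f"{self.patient_id}: negative alcohol units")


@dataclass
class Patient:
    """A patient with demographics and a time-ordered visit history.

    By convention the enrolment visit is at 0 months; validation requires
    only strictly increasing non-negative times so that time-shifted
    cohorts remain representable (only elapsed times matter downstream).
    """

    patient_id: str
    sex: str
    age_at_diagnosis: float
    disease_duration_at_enrolment: float
    ethnicity: str
    location: str
    post_secondary_education: Optional[bool] = None
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValidationError(f"{self.patient_id}: bad sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(
                f"{self.patient_id}: bad ethnicity {self.ethnicity!r}"
            )
        if self.location not in LOCATIONS:
            raise ValidationError(
                f"{self.patient_id}: bad location {self.location!r}"
            )
        times = [v.months_from_enrolment for v in self.visits]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"{self.patient_id}: visit times not strictly increasing"
            )
        for v in self.visits:
            if v.patient_id != self.patient_id:
                raise ValidationError(
                    f"{self.patient_id}: visit belongs to {v.patient_id!r}"
                )


@dataclass
class Cohort:
    patients: list[Patient] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = (
    "patient_id",
    "sex",
    "age_at_diagnosis",
    "disease_duration_at_enrolment",
    "ethnicity",
    "location",
    "post_secondary_education",
)

_BILAG_COLUMNS = tuple(f"bilag_{d}" for d in ORGAN_DOMAINS)
_AGENT_COLUMNS = (
    "azathioprine",
    "mycophenolate",
    "methotrexate",
    "cyclosporine",
    "cyclophosphamide_iv",
    "cyclophosphamide_oral",
    "other_is",
)

VISIT_COLUMNS = (
    ("patient_id", "months_from_enrolment")
    + _BILAG_COLUMNS
    + ("sledai_2k", "sdi", "oral_steroid_dose", "pulse_steroid", "antimalarial")
    + _AGENT_COLUMNS
    + (
        "biologic_any",
        "low_complement",
        "high_dsdna",
        "acl",
        "anti_b2gp1",
        "lupus_anticoagulant",
        "sf36_pcs",
        "sf36_mcs",
        "hypertension",
        "diabetes",
        "smoking_status",
        "alcohol_units_per_week",
    )
)

# maps CSV agent columns to Agent members ("other" clashes with future columns)
_AGENT_BY_COLUMN = {
    "azathioprine": Agent.azathioprine,
    "mycophenolate": Agent.mycophenolate,
    "methotrexate": Agent.methotrexate,
    "cyclosporine": Agent.cyclosporine,
    "cyclophosphamide_iv": Agent.cyclophosphamide_iv,
    "cyclophosphamide_oral": Agent.cyclophosphamide_oral,
    "other_is": Agent.other,
}
_COLUMN_BY_AGENT = {v: k for k, v in _AGENT_BY_COLUMN.items()}


def _parse_bool(cell: str, col: str, row: int) -> Optional[bool]:
    if cell == "":
        return None
    if cell == "0":
        return False
    if cell == "1":
        return True
    raise ParseError(f"column {col!r}: expected 0/1 or empty, got {cell!r}", row)


def _parse_float(cell: str, col: str, row: int) -> Optional[float]:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"column {col!r}: not a number: {cell!r}", row) from None


def _parse_int(cell: str, col: str, row: int) -> Optional[int]:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError:
        raise ParseError(f"column {col!r}: not an integer: {cell!r}", row) from None


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def _read_table(path, columns: tuple[str, ...], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParseError(f"{what} file missing columns: {sorted(missing)}")
    return df


def read_cohort(patients_path, visits_path) -> Cohort:
    """Read and validate a cohort from the two-file CSV schema.

    Visit rows are joined to patients on ``patient_id`` and sorted by
    ``months_from_enrolment``.  Empty cells map to the absent state, never
    to 0.  Raises :class:`ParseError` (with the 1-based data row),
    :class:`JoinError`, or :class:`ValidationError`.
    """
    pat_df = _read_table(patients_path, PATIENT_COLUMNS, "patients")
    vis_df = _read_table(visits_path, VISIT_COLUMNS, "visits")

    patients: dict[str, Patient] = {}
    for i, rec in enumerate(pat_df.to_dict("records"), start=1):
        pid = rec["patient_id"]
        if pid == "":
            raise ParseError("empty patient_id", i)
        if pid in patients:
            raise ValidationError(f"duplicate patient_id {pid!r} in patients file")
        if rec["sex"] not in ("female", "male"):
            raise ParseError(f"bad sex {rec['sex']!r}", i)
        if rec["ethnicity"] not in ETHNICITIES:
            raise ParseError(f"bad ethnicity {rec['ethnicity']!r}", i)
        if rec["location"] not in LOCATIONS:
            raise ParseError(f"bad location {rec['location']!r}", i)
        age = _parse_float(rec["age_at_diagnosis"], "age_at_diagnosis", i)
        dur = _parse_float(
            rec["disease_duration_at_enrolment"], "disease_duration_at_enrolment", i
        )
        if age is None or dur is None:
            raise ParseError("age and disease duration are mandatory", i)
        patients[pid] = Patient(
            patient_id=pid,
            sex=rec["sex"],
            age_at_diagnosis=age,
            disease_duration_at_enrolment=dur,
            ethnicity=rec["ethnicity"],
            location=rec["location"],
            post_secondary_education=_parse_bool(
                rec["post_secondary_education"], "post_secondary_education", i
            ),
        )

    visits_by_patient: dict[str, list[Visit]] = {pid: [] for pid in patients}
    for i, rec in enumerate(vis_df.to_dict("records"), start=1):
        pid = rec["patient_id"]
        if pid not in patients:
            raise JoinError(f"visits row {i}: unknown patient_id {pid!r}")
        months = _parse_float(rec["months_from_enrolment"], "months_from_enrolment", i)
        if months is None:
            raise ParseError("months_from_enrolment is mandatory", i)

        bilag_cells = [rec[c] for c in _BILAG_COLUMNS]
        if all(c == "" for c in bilag_cells):
            bilag = None
        elif any(c == "" for c in bilag_cells):
            raise ParseError(
                "partial BILAG assessment: grade all 8 domains or none", i
            )
        else:
            grades = {}
            for domain, cell in zip(ORGAN_DOMAINS, bilag_cells):
                try:
                    grades[domain] = Grade(cell)
                except ValueError:
                    raise ParseError(
                        f"column bilag_{domain}: bad grade {cell!r}", i
                    ) from None
            bilag = BILAGAssessment(**grades)

        agents = frozenset(
            agent
            for col, agent in _AGENT_BY_COLUMN.items()
            if _parse_bool(rec[col], col, i)
        )
        smoking_cell = rec["smoking_status"]
        if smoking_cell == "":
            smoking = None
        else:
            try:
                smoking = SmokingStatus(smoking_cell)
            except ValueError:
                raise ParseError(
                    f"bad smoking_status {smoking_cell!r}", i
                ) from None

        try:
            visit = Visit(
                patient_id=pid,
                months_from_enrolment=months,
                bilag=bilag,
                sledai_2k=_parse_int(rec["sledai_2k"], "sledai_2k", i),
                sdi=_parse_int(rec["sdi"], "sdi", i),
                oral_steroid_dose=_parse_float(
                    rec["oral_steroid_dose"], "oral_steroid_dose", i
                ),
                pulse_steroid=bool(_parse_bool(rec["pulse_steroid"], "pulse_steroid", i)),
                antimalarial=bool(_parse_bool(rec["antimalarial"], "antimalarial", i)),
                immunosuppressant_any=bool(agents),
                agents=agents,
                biologic_any=bool(_parse_bool(rec["biologic_any"], "biologic_any", i)),
                low_complement=_parse_bool(rec["low_complement"], "low_complement", i),
                high_dsdna=_parse_bool(rec["high_dsdna"], "high_dsdna", i),
                acl=_parse_bool(rec["acl"], "acl", i),
                anti_b2gp1=_parse_bool(rec["anti_b2gp1"], "anti_b2gp1", i),
                lupus_anticoagulant=_parse_bool(
                    rec["lupus_anticoagulant"], "lupus_anticoagulant", i
                ),
                sf36_pcs=_parse_float(rec["sf36_pcs"], "sf36_pcs", i),
                sf36_mcs=_parse_float(rec["sf36_mcs"], "sf36_mcs", i),
                hypertension=_parse_bool(rec["hypertension"], "hypertension", i),
                diabetes=_parse_bool(rec["diabetes"], "diabetes", i),
                smoking_status=smoking,
                alcohol_units_per_week=_parse_float(
                    rec["alcohol_units_per_week"], "alcohol_units_per_week", i
                ),
            )
        except ValidationError as exc:
            raise ParseError(str(exc), i) from exc
        visits_by_patient[pid].append(visit)

    cohort_patients = []
    for pid, patient in patients.items():
        vs = sorted(visits_by_patient[pid], key=lambda v: v.months_from_enrolment)
        times = [v.months_from_enrolment for v in vs]
        if len(times) != len(set(times)):
            raise ValidationError(
                f"duplicate (patient_id, months_from_enrolment) for {pid!r}"
            )
        cohort_patients.append(replace(patient, visits=vs))
    return Cohort(cohort_patients)


def _visit_row(v: Visit) -> dict[str, str]:
    row = {
        "patient_id": v.patient_id,
        "months_from_enrolment": _fmt(v.months_from_enrolment),
        "sledai_2k": _fmt(v.sledai_2k),
        "sdi": _fmt(v.sdi),
        "oral_steroid_dose": _fmt(v.oral_steroid_dose),
        "pulse_steroid": _fmt(v.pulse_steroid),
        "antimalarial": _fmt(v.antimalarial),
        "biologic_any": _fmt(v.biologic_any),
        "low_complement": _fmt(v.low_complement),
        "high_dsdna": _fmt(v.high_dsdna),
        "acl": _fmt(v.acl),
        "anti_b2gp1": _fmt(v.anti_b2gp1),
        "lupus_anticoagulant": _fmt(v.lupus_anticoagulant),
        "sf36_pcs": _fmt(v.sf36_pcs),
        "sf36_mcs": _fmt(v.sf36_mcs),
        "hypertension": _fmt(v.hypertension),
        "diabetes": _fmt(v.diabetes),
        "smoking_status": _fmt(v.smoking_status),
        "alcohol_units_per_week": _fmt(v.alcohol_units_per_week),
    }
    for domain, col in zip(ORGAN_DOMAINS, _BILAG_COLUMNS):
        row[col] = _fmt(v.bilag.grade(domain)) if v.bilag is not None else ""
    for agent, col in _COLUMN_BY_AGENT.items():
        row[col] = "1" if agent in v.agents else "0"
    return row


def write_cohort(cohort: Cohort, patients_path, visits_path) -> None:
    """Write a cohort to the two-file CSV schema (lossless round trip)."""
    pat_rows = [
        {
            "patient_id": p.patient_id,
            "sex": p.sex,
            "age_at_diagnosis": _fmt(p.age_at_diagnosis),
            "disease_duration_at_enrolment": _fmt(p.disease_duration_at_enrolment),
            "ethnicity": p.ethnicity,
            "location": p.location,
            "post_secondary_education": _fmt(p.post_secondary_education),
        }
        for p in cohort.patients
    ]
    vis_rows = [_visit_row(v) for p in cohort.patients for v in p.visits]
    pd.DataFrame(pat_rows, columns=list(PATIENT_COLUMNS)).to_csv(
        patients_path, index=False
    )
    pd.DataFrame(vis_rows, columns=list(VISIT_COLUMNS)).to_csv(
        visits_path, index=False
    )
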