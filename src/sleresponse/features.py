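"""Baseline predictor encodings for the response models.

Predictors measured at the index visit are encoded with explicit
reference levels: Canada for location, Caucasian for ethnicity, never-
smokers for smoking, the low steroid band for dose (strict <7.5 mg/day in
the inception coding, <=7.5 mg/day in the active-disease coding), zero
active domains (inception) or one (active disease) for the BILAG A/B
count, and SDI 0 for damage.  Age at diagnosis enters centred at 35
years; SLEDAI-2K enters linearly, optionally with a quadratic term
computed after centring at the sample mean to curb collinearity.

Missing predictor values are kept first-class: alcohol merges "0 or not
recorded" into its reference level (the only merge the source tables
evidence); SDI's heavy missingness gets its own "NA" dummy; every other
missing value is filled (median for continuous, mode for binary) with a
companion ``*_missing`` indicator so the analysis row count is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import Agent, ORGAN_DOMAINS, ValidationError
from .outcomes import ActivityCount, OutcomeLabel, count_ab
from .cohorts import IndexPair, LabelledCohort

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "DegenerateOutcomeError",
    "encode_age",
    "encode_dose_band",
    "encode_alcohol",
    "encode_counts_bands",
    "encode_baseline",
    "build_design_matrix",
]

AGE_CENTRE = 35.0  # years; odds ratios read as per one-year increase from 35
SF36_THRESHOLD = 40.0

REFERENCE_LEVELS = {
    "sex": "female",
    "ethnicity": "Caucasian",
    "location": "Canada",
    "dose_band": "low",
    "ab_count_band": {"inception": "0", "active_disease": "1"},
    "sdi_band": "0",
    "alcohol_band": "zero_or_missing",
    "smoking_status": "never",
}


class DegenerateOutcomeError(ValidationError):
    """All classifiable outcomes fell in one class; no model is fittable."""


@dataclass(frozen=True)
class FeatureSpec:
    """How to encode baseline predictors for one analysis cohort."""

    cohort_tag: str = "inception"
    sledai_quadratic: bool = False
    center_sledai: bool = True  # only relevant when sledai_quadratic
    include: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.cohort_tag not in ("inception", "active_disease"):
            raise ValidationError(f"bad cohort_tag {self.cohort_tag!r}")

    @property
    def reference_levels(self) -> dict:
        levels = dict(REFERENCE_LEVELS)
        levels["ab_count_band"] = REFERENCE_LEVELS["ab_count_band"][self.cohort_tag]
        return levels


@dataclass
class FeatureMatrix:
    """Encoded design matrix with labels and missingness bookkeeping."""

    X: pd.DataFrame  # rows indexed by patient_id, numeric columns
    y: pd.Series  # 1 = achieved, 0 = not_achieved
    missing_mask: pd.DataFrame  # True where the source value was absent
    meta: dict

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def encode_age(age_at_diagnosis: float) -> float:
    """Age at diagnosis centred at 35 years."""
    return age_at_diagnosis - AGE_CENTRE


def encode_dose_band(dose: Optional[float], cohort_tag: str) -> str:
    """Band the average oral prednisolone-equivalent dose (mg/day).

    Inception coding: low <7.5, medium [7.5, 30], high >30.  Active-
    disease coding: low <=7.5, moderate (7.5, 30], high >30.  An absent
    dose is banded low: patients not on oral steroids carry no recorded
    dose.
    """
    if dose is not None and dose < 0:
        raise ValidationError("negative steroid dose")
    if dose is None:
        return "low"
    if dose > 30:
        return "high"
    if cohort_tag == "inception":
        return "medium" if dose >= 7.5 else "low"
    return "moderate" if dose > 7.5 else "low"


def encode_alcohol(units: Optional[float]) -> str:
    """Weekly alcohol in three levels; zero and unrecorded share the reference."""
    if units is not None and units < 0:
        raise ValidationError("negative alcohol units")
    if units is None or units == 0:
        return "zero_or_missing"
    return "low" if units <= 4 else "high"


def encode_counts_bands(count: ActivityCount, cohort_tag: str) -> str:
    """Band the number of active (A/B) domains.

    Inception levels {0 (ref), 1, ge2}; active-disease levels {1 (ref),
    ge2} — zero is impossible there by construction.
    """
    total = count.total
    if cohort_tag == "active_disease":
        if total == 0:
            raise ValidationError(
                "active_disease pair with zero active domains (cohort bug)"
            )
        return "1" if total == 1 else "ge2"
    if total == 0:
        return "0"
    return "1" if total == 1 else "ge2"


_CONTINUOUS = {"age_minus35", "disease_duration", "sledai"}


def _base_record(pair: IndexPair, spec: FeatureSpec) -> dict:
    p, v = pair.patient, pair.index_visit
    assert v.bilag is not None
    rec: dict = {
        "sex_male": int(p.sex == "male"),
        "age_minus35": encode_age(p.age_at_diagnosis),
        "disease_duration": p.disease_duration_at_enrolment,
    }
    for eth in ("Hispanic", "Asian", "African", "Other"):
        rec[f"ethnicity_{eth.lower()}"] = int(p.ethnicity == eth)
    for loc in ("United States", "Mexico", "Europe", "Asia"):
        rec[f"location_{loc.lower().replace(' ', '_')}"] = int(p.location == loc)
    rec["post_secondary_education"] = (
        None if p.post_secondary_education is None else int(p.post_secondary_education)
    )

    band = encode_dose_band(v.oral_steroid_dose, spec.cohort_tag)
    if spec.cohort_tag == "inception":
        rec["dose_medium"] = int(band == "medium")
        rec["dose_high"] = int(band == "high")
    else:
        rec["dose_moderate"] = int(band == "moderate")
        rec["dose_high"] = int(band == "high")
    rec["pulse_steroid"] = int(v.pulse_steroid)
    rec["antimalarial"] = int(v.antimalarial)
    rec["immunosuppressant_any"] = int(v.immunosuppressant_any)
    for agent in Agent:
        rec[f"agent_{agent.value}"] = int(agent in v.agents)
    rec["biologic_any"] = int(v.biologic_any)

    count_band = encode_counts_bands(count_ab(v.bilag), spec.cohort_tag)
    if spec.cohort_tag == "inception":
        rec["ab_count_1"] = int(count_band == "1")
    rec["ab_count_ge2"] = int(count_band == "ge2")
    for d in ORGAN_DOMAINS:
        rec[f"bilag_{d}_ab"] = int(v.bilag.grade(d).is_active)

    rec["sledai"] = None if v.sledai_2k is None else float(v.sledai_2k)
    if v.sdi is None:
        sdi_band = "na"
    elif v.sdi == 0:
        sdi_band = "0"
    elif v.sdi == 1:
        sdi_band = "1"
    else:
        sdi_band = "ge2"
    rec["sdi_1"] = int(sdi_band == "1")
    rec["sdi_ge2"] = int(sdi_band == "ge2")
    rec["sdi_na"] = int(sdi_band == "na")

    for name in ("high_dsdna", "low_complement", "acl", "anti_b2gp1",
                 "lupus_anticoagulant", "hypertension", "diabetes"):
        val = getattr(v, name)
        rec[name] = None if val is None else int(val)

    alc = encode_alcohol(v.alcohol_units_per_week)
    rec["alcohol_low"] = int(alc == "low")
    rec["alcohol_high"] = int(alc == "high")
    smoking = None if v.smoking_status is None else v.smoking_status.value
    rec["smoking_current"] = None if smoking is None else int(smoking == "current")
    rec["smoking_previous"] = None if smoking is None else int(smoking == "previous")
    rec["sf36_pcs_ge40"] = (
        None if v.sf36_pcs is None else int(v.sf36_pcs >= SF36_THRESHOLD)
    )
    rec["sf36_mcs_ge40"] = (
        None if v.sf36_mcs is None else int(v.sf36_mcs >= SF36_THRESHOLD)
    )
    return rec


def _fill_value(col: str, series: pd.Series) -> float:
    observed = series.dropna()
    if observed.empty:
        return 0.0
    if col in _CONTINUOUS:
        return float(observed.median())
    # mode; ties broken toward the smaller value for determinism
    counts = observed.value_counts()
    top = counts[counts == counts.max()]
    return float(min(top.index))


def encode_baseline(
    pairs: list[IndexPair], spec: FeatureSpec
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Encode index-visit predictors for a list of pairs.

    Returns ``(X, missing_mask, meta)``; no outcome involved, so this is
    usable both for model design matrices and for simulation ground
    truth.  Column naming and order are stable across runs; row order
    follows the input.
    """
    if not pairs:
        raise ValidationError("no pairs to encode")
    tags = {p.cohort_tag for p in pairs}
    if tags != {spec.cohort_tag}:
        raise ValidationError(
            f"pairs tagged {sorted(tags)} but spec is for {spec.cohort_tag!r}"
        )
    records = [_base_record(p, spec) for p in pairs]
    ids = [p.patient.patient_id for p in pairs]
    raw = pd.DataFrame.from_records(records, index=pd.Index(ids, name="patient_id"))
    raw = raw.astype("float64")

    missing = raw.isna()
    fills: dict[str, float] = {}
    columns: list[str] = []
    out: dict[str, pd.Series] = {}
    for col in raw.columns:
        series = raw[col]
        columns.append(col)
        if missing[col].any():
            fills[col] = _fill_value(col, series)
            out[col] = series.fillna(fills[col])
            ind = f"{col}_missing"
            out[ind] = missing[col].astype("float64")
            columns.append(ind)
        else:
            out[col] = series

    X = pd.DataFrame(out, columns=columns)

    sledai_meta: dict = {}
    if spec.sledai_quadratic:
        s = X["sledai"]
        centre = float(s.mean()) if spec.center_sledai else 0.0
        sc = s - centre
        pos = X.columns.get_loc("sledai")
        X = X.drop(columns=["sledai"])
        X.insert(pos, "sledai_c", sc)
        X.insert(pos + 1, "sledai_c_sq", sc**2)
        sledai_meta = {"sledai_centre": centre}

    if spec.include is not None:
        keep = [
            c
            for c in X.columns
            if c in spec.include or c.removesuffix("_missing") in spec.include
        ]
        X = X[keep]

    meta = {
        "cohort_tag": spec.cohort_tag,
        "reference_levels": REFERENCE_LEVELS,
        "fills": fills,
        "n_rows": len(X),
        **sledai_meta,
    }
    return X, missing.reindex(columns=X.columns, fill_value=False), meta


def build_design_matrix(labelled: LabelledCohort, spec: FeatureSpec) -> FeatureMatrix:
    """Design matrix over the classifiable pairs of a labelled cohort.

    Unclassifiable pairs are dropped before modelling; the outcome vector
    codes achieved as 1 and not_achieved as 0.  Raises
    :class:`DegenerateOutcomeError` when only one class remains.
    """
    if not labelled.pairs:
        raise ValidationError("empty labelled cohort")
    kept = [
        (pair, label)
        for pair, label in zip(labelled.pairs, labelled.labels)
        if label is not OutcomeLabel.unclassifiable
    ]
    if not kept:
        raise DegenerateOutcomeError("no classifiable pairs")
    pairs = [p for p, _ in kept]
    y = pd.Series(
        [int(label is OutcomeLabel.achieved) for _, label in kept],
        index=pd.Index([p.patient.patient_id for p in pairs], name="patient_id"),
        name=labelled.outcome_name,
        dtype="int64",
    )
    if y.nunique() < 2:
        raise DegenerateOutcomeError(
            f"outcome {labelled.outcome_name!r} is single-class "
            f"({y.iloc[0]}) over {len(y)} classifiable pairs"
        )
    X, mask, meta = encode_baseline(pairs, spec)
    meta["outcome_name"] = labelled.outcome_name
    return FeatureMatrix(X=X, y=y, missing_mask=mask, meta=meta)
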