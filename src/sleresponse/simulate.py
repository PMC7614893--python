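"""Synthetic SLE registry cohorts with known ground truth.

Real inception-registry patient data are not public, so every pipeline
stage is exercised on simulated cohorts whose baseline marginals emulate
published registry characteristics (89% female, per-domain BILAG A/B
prevalences such as renal 52% and haematological 44%, 65-68%
antimalarial use, ...) and whose 12-month outcome is generated from a
logistic model with *planted* log-odds coefficients — by default the
logs of published univariate odds ratios, used as an illustrative signal
rather than an estimate of any real generating process.  The intercept
is solved numerically so the population mean response probability hits a
target prevalence (default 28%).

Follow-up visits are materialized to satisfy the intended Major Clinical
Response label *by construction* (achieved: all domains C/D, dose
<= 7.5 mg, SLEDAI-2K <= 4; not achieved: at least one criterion violated
at random), so outcome classification reproduces the planted labels
exactly wherever a follow-up exists; a configurable fraction of
follow-ups (default 7%) is missing.  Improvement labels are computed,
never planted — planting both outcomes jointly is over-constrained.

Predictors are sampled independently; real-world collinearity (e.g.
dose x immunosuppressant use) is deliberately absent.  The module also
provides generic planted-effect logistic designs
(:func:`sample_planted_design`) and Monte-Carlo oracle AUCs
(:func:`theoretical_auc`) — the performance ceiling any fitted model can
approach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import (
    Agent,
    BILAGAssessment,
    Cohort,
    Grade,
    ORGAN_DOMAINS,
    Patient,
    SmokingStatus,
    ValidationError,
    Visit,
)
from .cohorts import build_inception_cohort
from .features import FeatureSpec, encode_baseline
from .selection import compute_auc

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "GroundTruth",
    "PlantedDataset",
    "default_outcome_model",
    "sample_baseline",
    "assign_outcomes",
    "materialize_followups",
    "generate_cohort",
    "theoretical_auc",
    "sample_planted_design",
    "planted_theoretical_auc",
]


class ConfigError(ValidationError):
    """A generator configuration value is out of range or inconsistent."""


def default_outcome_model() -> dict[str, float]:
    """Planted log-odds coefficients: logs of published univariate ORs for
    the inception-cohort MCR predictors, zero elsewhere."""
    ors = {
        "age_minus35": 1.021,
        "location_europe": 1.581,
        "ethnicity_african": 0.385,
        "alcohol_low": 1.733,
        "smoking_current": 1.448,
        "ab_count_1": 0.465,
        "ab_count_ge2": 0.161,
        "bilag_musculoskeletal_ab": 0.378,
        "bilag_haematological_ab": 0.324,
        "sledai": 0.831,
        "sdi_1": 0.401,
        "sf36_pcs_ge40": 1.750,
        "immunosuppressant_any": 0.430,
        "agent_azathioprine": 0.470,
        "agent_cyclophosphamide_iv": 0.206,
        "antimalarial": 2.392,
        "dose_high": 0.183,
        "dose_medium": 0.500,
    }
    return {k: math.log(v) for k, v in ors.items()}


def _default_domain_activity() -> dict[str, float]:
    # per-domain P(A or B) at the index visit
    return {
        "constitutional": 0.17,
        "mucocutaneous": 0.34,
        "neuropsychiatric": 0.06,
        "musculoskeletal": 0.36,
        "cardiorespiratory": 0.05,
        "vasculitis": 0.09,
        "renal": 0.52,
        "haematological": 0.44,
    }


def _default_missing_rates() -> dict[str, float]:
    # per-field fraction of index visits with the value unrecorded
    return {
        "post_secondary_education": 0.05,
        "sledai_2k": 0.003,
        "low_complement": 0.07,
        "high_dsdna": 0.075,
        "acl": 0.36,
        "anti_b2gp1": 0.36,
        "lupus_anticoagulant": 0.34,
        "sf36_pcs": 0.15,
        "sf36_mcs": 0.15,
        "hypertension": 0.03,
        "diabetes": 0.61,
        "smoking_status": 0.001,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Marginal defaults follow published registry baseline tables; the
    outcome model plants log-odds effects on encoded baseline predictor
    columns, calibrated to ``target_prevalence``.
    """

    n_patients: int = 1500
    seed: int = 0
    female_prob: float = 0.89
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Caucasian": 0.50,
            "Hispanic": 0.13,
            "Asian": 0.16,
            "African": 0.17,
            "Other": 0.04,
        }
    )
    location_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Canada": 0.232,
            "United States": 0.285,
            "Mexico": 0.098,
            "Europe": 0.281,
            "Asia": 0.104,
        }
    )
    age_log_median: float = math.log(32.4)
    age_log_sigma: float = 0.43
    duration_log_median: float = math.log(0.40)
    duration_log_sigma: float = 1.10
    education_prob: float = 0.63
    domain_activity_probs: Mapping[str, float] = field(
        default_factory=_default_domain_activity
    )
    p_a_given_active: float = 0.30
    inactive_grade_probs: tuple[float, float, float] = (0.25, 0.45, 0.30)  # C, D, E
    sledai_gamma_shape: float = 1.8
    sledai_gamma_scale: float = 4.5
    sdi_probs: Mapping[str, float] = field(
        default_factory=lambda: {"0": 0.309, "1": 0.052, "ge2": 0.030, "na": 0.609}
    )
    dose_nonzero_prob: float = 0.69  # patients not on oral steroids carry no dose
    dose_log_median: float = math.log(15.0)
    dose_log_sigma: float = 0.90
    pulse_prob: float = 0.05
    antimalarial_prob: float = 0.66
    agent_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "azathioprine": 0.16,
            "mycophenolate": 0.07,
            "methotrexate": 0.08,
            "cyclosporine": 0.02,
            "cyclophosphamide_iv": 0.06,
            "cyclophosphamide_oral": 0.005,
            "other": 0.02,
        }
    )
    biologic_prob: float = 0.014
    serology_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "low_complement": 0.40,
            "high_dsdna": 0.43,
            "acl": 0.13,
            "anti_b2gp1": 0.14,
            "lupus_anticoagulant": 0.21,
        }
    )
    sf36_pcs_mean: float = 39.2
    sf36_pcs_sd: float = 12.5
    sf36_mcs_mean: float = 45.0
    sf36_mcs_sd: float = 14.8
    hypertension_prob: float = 0.40
    diabetes_prob: float = 0.03
    smoking_probs: Mapping[str, float] = field(
        default_factory=lambda: {"current": 0.15, "previous": 0.20, "never": 0.65}
    )
    alcohol_drinker_prob: float = 0.35
    alcohol_mean_units: float = 3.2  # exponential mean among drinkers
    missing_field_rates: Mapping[str, float] = field(
        default_factory=_default_missing_rates
    )
    outcome_model: Mapping[str, float] = field(default_factory=default_outcome_model)
    target_prevalence: float = 0.28
    missing_followup_rate: float = 0.07
    followup_jitter: float = 1.5  # months around 12

    def __post_init__(self):
        probs = [
            self.female_prob,
            self.education_prob,
            self.p_a_given_active,
            self.dose_nonzero_prob,
            self.pulse_prob,
            self.antimalarial_prob,
            self.biologic_prob,
            self.hypertension_prob,
            self.diabetes_prob,
            self.alcohol_drinker_prob,
            self.missing_followup_rate,
            *self.ethnicity_probs.values(),
            *self.location_probs.values(),
            *self.domain_activity_probs.values(),
            *self.inactive_grade_probs,
            *self.sdi_probs.values(),
            *self.agent_probs.values(),
            *self.serology_probs.values(),
            *self.smoking_probs.values(),
            *self.missing_field_rates.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if not 0 < self.target_prevalence < 1:
            raise ConfigError("target_prevalence must lie in (0, 1)")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        for mapping, expected in (
            (self.domain_activity_probs, set(ORGAN_DOMAINS)),
            (self.ethnicity_probs, {"Caucasian", "Hispanic", "Asian", "African", "Other"}),
        ):
            if set(mapping) != expected:
                raise ConfigError(f"category keys {set(mapping)} != {expected}")


@dataclass
class GroundTruth:
    """Planted outcome mechanism and per-patient latent state.

    ``table`` is indexed by patient_id with columns ``linear_predictor``
    (excluding intercept), ``prob``, ``u`` (the recorded uniform draw)
    and ``intended_mcr``; labels reproduce as ``u < prob``.
    """

    table: pd.DataFrame
    coefficients: dict[str, float]
    intercept: float
    target_prevalence: float


def _choice(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _maybe_missing(rng, rates: Mapping[str, float], name: str, value):
    rate = rates.get(name, 0.0)
    if rate and rng.random() < rate:
        return None
    return value


def _sample_assessment(cfg: GeneratorConfig, rng) -> BILAGAssessment:
    grades = {}
    pc, pd_, _pe = cfg.inactive_grade_probs
    for d in ORGAN_DOMAINS:
        if rng.random() < cfg.domain_activity_probs[d]:
            grades[d] = Grade.A if rng.random() < cfg.p_a_given_active else Grade.B
        else:
            u = rng.random() * sum(cfg.inactive_grade_probs)
            grades[d] = Grade.C if u < pc else (Grade.D if u < pc + pd_ else Grade.E)
    return BILAGAssessment(**grades)


def sample_baseline(config: GeneratorConfig) -> Cohort:
    """Draw ``n_patients`` patients with index (enrolment) visits only.

    All marginals are sampled independently from the configured
    distributions; deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rates = config.missing_field_rates
    patients = []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        sledai = int(
            min(105, round(rng.gamma(config.sledai_gamma_shape, config.sledai_gamma_scale)))
        )
        sdi_band = _choice(rng, config.sdi_probs)
        sdi = {"0": 0, "1": 1}.get(sdi_band)
        if sdi_band == "ge2":
            sdi = 2 if rng.random() < 0.7 else 3
        dose = (
            float(rng.lognormal(config.dose_log_median, config.dose_log_sigma))
            if rng.random() < config.dose_nonzero_prob
            else None
        )
        agents = frozenset(
            Agent(a) for a, p in config.agent_probs.items() if rng.random() < p
        )
        smoking = _maybe_missing(
            rng, rates, "smoking_status", SmokingStatus(_choice(rng, config.smoking_probs))
        )
        alcohol = (
            float(rng.exponential(config.alcohol_mean_units))
            if rng.random() < config.alcohol_drinker_prob
            else 0.0
        )
        visit = Visit(
            patient_id=pid,
            months_from_enrolment=0.0,
            bilag=_sample_assessment(config, rng),
            sledai_2k=_maybe_missing(rng, rates, "sledai_2k", sledai),
            sdi=sdi,
            oral_steroid_dose=dose,
            pulse_steroid=bool(rng.random() < config.pulse_prob),
            antimalarial=bool(rng.random() < config.antimalarial_prob),
            immunosuppressant_any=bool(agents),
            agents=agents,
            biologic_any=bool(rng.random() < config.biologic_prob),
            low_complement=_maybe_missing(
                rng, rates, "low_complement",
                bool(rng.random() < config.serology_probs["low_complement"]),
            ),
            high_dsdna=_maybe_missing(
                rng, rates, "high_dsdna",
                bool(rng.random() < config.serology_probs["high_dsdna"]),
            ),
            acl=_maybe_missing(
                rng, rates, "acl", bool(rng.random() < config.serology_probs["acl"])
            ),
            anti_b2gp1=_maybe_missing(
                rng, rates, "anti_b2gp1",
                bool(rng.random() < config.serology_probs["anti_b2gp1"]),
            ),
            lupus_anticoagulant=_maybe_missing(
                rng, rates, "lupus_anticoagulant",
                bool(rng.random() < config.serology_probs["lupus_anticoagulant"]),
            ),
            sf36_pcs=_maybe_missing(
                rng, rates, "sf36_pcs",
                float(rng.normal(config.sf36_pcs_mean, config.sf36_pcs_sd)),
            ),
            sf36_mcs=_maybe_missing(
                rng, rates, "sf36_mcs",
                float(rng.normal(config.sf36_mcs_mean, config.sf36_mcs_sd)),
            ),
            hypertension=_maybe_missing(
                rng, rates, "hypertension",
                bool(rng.random() < config.hypertension_prob),
            ),
            diabetes=_maybe_missing(
                rng, rates, "diabetes", bool(rng.random() < config.diabetes_prob)
            ),
            smoking_status=smoking,
            alcohol_units_per_week=alcohol,
        )
        patients.append(
            Patient(
                patient_id=pid,
                sex="female" if rng.random() < config.female_prob else "male",
                age_at_diagnosis=float(
                    rng.lognormal(config.age_log_median, config.age_log_sigma)
                ),
                disease_duration_at_enrolment=float(
                    rng.lognormal(config.duration_log_median, config.duration_log_sigma)
                ),
                ethnicity=_choice(rng, config.ethnicity_probs),
                location=_choice(rng, config.location_probs),
                post_secondary_education=_maybe_missing(
                    rng, rates, "post_secondary_education",
                    bool(rng.random() < config.education_prob),
                ),
                visits=[visit],
            )
        )
    return Cohort(patients)


def calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept at which the mean response probability equals ``target``."""
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ConfigError("non-finite linear predictor")
    return float(brentq(lambda b0: expit(b0 + lp).mean() - target, -40.0, 40.0))


def _encoded_baseline(config: GeneratorConfig, cohort: Cohort) -> pd.DataFrame:
    pairs = build_inception_cohort(cohort)
    X, _, _ = encode_baseline(pairs, FeatureSpec(cohort_tag="inception"))
    return X


def assign_outcomes(
    config: GeneratorConfig, baselines: Cohort, features: Optional[pd.DataFrame] = None
) -> GroundTruth:
    """Plant the intended MCR labels from the configured logistic model.

    ``features`` defaults to the inception-coded baseline design matrix
    of ``baselines``; coefficient keys must be feature columns.
    """
    X = _encoded_baseline(config, baselines) if features is None else features
    unknown = set(config.outcome_model) - set(X.columns)
    if unknown:
        raise ConfigError(f"outcome_model names unknown columns: {sorted(unknown)}")
    coefs = dict(config.outcome_model)
    lp = np.zeros(len(X)) if not coefs else (
        X[list(coefs)].to_numpy() @ np.asarray(list(coefs.values()))
    )
    intercept = calibrate_intercept(lp, config.target_prevalence)
    prob = expit(intercept + lp)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    u = rng.random(len(X))
    table = pd.DataFrame(
        {
            "linear_predictor": lp,
            "prob": prob,
            "u": u,
            "intended_mcr": (u < prob).astype(int),
        },
        index=X.index,
    )
    return GroundTruth(
        table=table,
        coefficients=coefs,
        intercept=intercept,
        target_prevalence=config.target_prevalence,
    )


_VIOLATIONS = ("bilag", "dose", "sledai")


def _followup_visit(
    baseline: Visit, intended: bool, cfg: GeneratorConfig, rng
) -> Visit:
    months = baseline.months_from_enrolment + 12.0 + float(
        rng.uniform(-cfg.followup_jitter, cfg.followup_jitter)
    )
    violations = set()
    if not intended:
        mask = int(rng.integers(1, 2 ** len(_VIOLATIONS)))  # non-empty subset
        violations = {v for i, v in enumerate(_VIOLATIONS) if mask >> i & 1}

    grades = {
        d: (Grade.C if rng.random() < 0.6 else Grade.D) for d in ORGAN_DOMAINS
    }
    if "bilag" in violations:
        k = int(rng.integers(1, 4))
        for d in rng.choice(len(ORGAN_DOMAINS), size=k, replace=False):
            grades[ORGAN_DOMAINS[d]] = Grade.A if rng.random() < 0.4 else Grade.B
    dose = (
        float(rng.uniform(8.0, 40.0))
        if "dose" in violations
        else (0.0 if rng.random() < 0.5 else float(rng.uniform(0.0, 7.5)))
    )
    sledai = (
        int(rng.integers(5, 21)) if "sledai" in violations else int(rng.integers(0, 5))
    )
    return Visit(
        patient_id=baseline.patient_id,
        months_from_enrolment=months,
        bilag=BILAGAssessment(**grades),
        sledai_2k=sledai,
        sdi=baseline.sdi,
        oral_steroid_dose=dose,
        pulse_steroid=baseline.pulse_steroid,
        antimalarial=baseline.antimalarial,
        immunosuppressant_any=baseline.immunosuppressant_any,
        agents=baseline.agents,
        biologic_any=baseline.biologic_any,
        low_complement=baseline.low_complement,
        high_dsdna=baseline.high_dsdna,
        acl=baseline.acl,
        anti_b2gp1=baseline.anti_b2gp1,
        lupus_anticoagulant=baseline.lupus_anticoagulant,
        sf36_pcs=baseline.sf36_pcs,
        sf36_mcs=baseline.sf36_mcs,
        hypertension=baseline.hypertension,
        diabetes=baseline.diabetes,
        smoking_status=baseline.smoking_status,
        alcohol_units_per_week=baseline.alcohol_units_per_week,
    )


def materialize_followups(
    baselines: Cohort, truth: GroundTruth, config: GeneratorConfig
) -> Cohort:
    """Append ~12-month follow-up visits realizing the intended MCR labels.

    A ``missing_followup_rate`` fraction of patients get no follow-up
    visit (these become unclassifiable downstream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    patients = []
    for p in baselines:
        baseline = p.visits[0]
        visits = list(p.visits)
        if rng.random() >= config.missing_followup_rate:
            intended = bool(truth.table.loc[p.patient_id, "intended_mcr"])
            visits.append(_followup_visit(baseline, intended, config, rng))
        patients.append(dc_replace(p, visits=visits))
    return Cohort(patients)


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Full generation: baselines, planted outcomes, follow-up visits."""
    baselines = sample_baseline(config)
    truth = assign_outcomes(config, baselines)
    return materialize_followups(baselines, truth, config), truth


def theoretical_auc(config: GeneratorConfig, n_mc: int = 50_000, seed: int = 0) -> float:
    """Monte-Carlo AUC of the *true* linear predictor against labels it
    generates — the ceiling any fitted model can approach."""
    mc_cfg = dc_replace(config, n_patients=n_mc, seed=seed)
    baselines = sample_baseline(mc_cfg)
    truth = assign_outcomes(mc_cfg, baselines)
    t = truth.table
    return compute_auc(t["linear_predictor"].to_numpy(), t["intended_mcr"].to_numpy())


# ---------------------------------------------------------------------------
# Generic planted-effect logistic designs (for calibration/recovery studies)
# ---------------------------------------------------------------------------


@dataclass
class PlantedDataset:
    """Independent standard-normal design with a planted logistic outcome."""

    X: pd.DataFrame
    y: np.ndarray
    linear_predictor: np.ndarray
    intercept: float
    coefs: np.ndarray

    @property
    def planted(self) -> list[str]:
        return [c for c, b in zip(self.X.columns, self.coefs) if b != 0.0]


def sample_planted_design(
    n: int, coefs, prevalence: float = 0.5, seed: int = 0
) -> PlantedDataset:
    """Draw ``n`` rows of independent N(0,1) features and Bernoulli
    outcomes from ``logit p = b0 + X @ coefs`` with ``b0`` calibrated so
    the sample mean probability equals ``prevalence``."""
    coefs = np.asarray(coefs, dtype=float)
    if not 0 < prevalence < 1:
        raise ConfigError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    X = rng.standard_normal((n, coefs.size))
    lp = X @ coefs
    intercept = calibrate_intercept(lp, prevalence)
    y = (rng.random(n) < expit(intercept + lp)).astype(int)
    return PlantedDataset(
        X=pd.DataFrame(X, columns=[f"x{j}" for j in range(coefs.size)]),
        y=y,
        linear_predictor=lp,
        intercept=intercept,
        coefs=coefs,
    )


def planted_theoretical_auc(
    coefs, prevalence: float = 0.5, n_mc: int = 200_000, seed: int = 0
) -> float:
    """Monte-Carlo oracle AUC for :func:`sample_planted_design` conditions."""
    d = sample_planted_design(n_mc, coefs, prevalence, seed)
    if d.y.min() == d.y.max():  # no signal and extreme prevalence edge case
        raise ConfigError("degenerate Monte-Carlo draw; increase n_mc")
    return compute_auc(d.linear_predictor, d.y)
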