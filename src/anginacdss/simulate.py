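"""Synthetic clinic cohorts and a generative model of the care pathway.

No patient-level data accompany the study this package operationalises, so
every downstream computation is exercised on synthetic cohorts. The generator
draws independent marginals matching a chest-pain-clinic case mix: ages from
a truncated normal, sex/risk-factor/medication flags from Bernoulli draws,
and the three pain answers *conditionally on a sampled typicality category*
(sample the category, then a uniformly random boolean triple consistent with
it) so the induced typicality distribution hits the configured marginals
exactly in expectation — independent per-answer draws could not.

The pathway model is deliberately minimal: whether any qualifying
investigation happens within six months is a Bernoulli draw whose probability
depends only on whether one was recommended, and each newly recommended
medication class is adopted independently. Risk-factor correlations, clinician
heterogeneity and site effects are not modelled.

Randomness is driven by a single global seed; each stage (cohort, CDSS-use
flags, pathway) uses a named substream so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import truncnorm

from .engine import run_cdss_batch
from .model import (
    AGE_MAX,
    AGE_MIN,
    FollowUpOutcome,
    Group,
    GuidelineConfig,
    Investigation,
    InvestigationDone,
    MedClass,
    PatientPresentation,
    Recommendation,
    RiskLevel,
    Sex,
    Typicality,
)
from .stats import (
    ConcordanceSummary,
    LinkageError,
    MedDeltaSummary,
    investigation_concordance,
    medication_delta_summary,
)

__all__ = [
    "CohortGenConfig",
    "AdherenceModel",
    "generate_cohort",
    "simulate_pathway",
    "run_study",
    "StudyData",
    "concordance_records_from_counts",
    "med_delta_records_from_counts",
]

# fixed substream labels so each stage draws from its own independent stream
_STAGE = {"cohort": 0, "cdss_use": 1, "pathway": 2}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE[stage],))
    )


class CohortGenConfig(BaseModel):
    """Marginal distributions for a synthetic clinic cohort.

    Defaults reproduce the case mix of a UK rapid-access chest pain clinic
    population: mean age 59.4 (SD 11.0) years, 49% male, smoking 41%,
    diabetes 8%, hyperlipidaemia 32%, pain typicality 19% typical / 16%
    atypical / 65% non-anginal, baseline secondary-prevention classes
    antiplatelet 22% / beta-blocker 5% / statin 25%. ECG-abnormality
    prevalence is not reported for that population; the 10% default is an
    assumption (see the methods note).
    """

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=0, default=106)
    age_mean: float = 59.4
    age_sd: float = Field(gt=0.0, default=11.0)
    p_male: float = Field(ge=0.0, le=1.0, default=0.49)
    p_smoker: float = Field(ge=0.0, le=1.0, default=0.41)
    p_diabetes: float = Field(ge=0.0, le=1.0, default=0.08)
    p_hyperlipidaemia: float = Field(ge=0.0, le=1.0, default=0.32)
    p_ecg_abnormal: float = Field(ge=0.0, le=1.0, default=0.10)
    typicality_probs: tuple[float, float, float] = (0.19, 0.16, 0.65)
    p_baseline_antiplatelet: float = Field(ge=0.0, le=1.0, default=0.22)
    p_baseline_beta_blocker: float = Field(ge=0.0, le=1.0, default=0.05)
    p_baseline_statin: float = Field(ge=0.0, le=1.0, default=0.25)
    group: Group = Group.before
    site: str = "synthetic"
    seed: int = 0

    @model_validator(mode="after")
    def _check_probs(self) -> "CohortGenConfig":
        if any(not 0.0 <= p <= 1.0 for p in self.typicality_probs):
            raise ValueError(f"typicality_probs outside [0,1]: {self.typicality_probs}")
        if abs(sum(self.typicality_probs) - 1.0) > 1e-9:
            raise ValueError(
                f"typicality_probs must sum to 1, got {sum(self.typicality_probs)}"
            )
        return self


class AdherenceModel(BaseModel):
    """Behavioural probabilities of the simulated clinic pathway."""

    model_config = ConfigDict(frozen=True)

    p_follow_investigation_recommended: float = Field(ge=0.0, le=1.0, default=0.59)
    p_investigate_when_not_recommended: float = Field(ge=0.0, le=1.0, default=0.14)
    p_follow_medication: float = Field(ge=0.0, le=1.0, default=0.50)
    p_cdss_used: float = Field(ge=0.0, le=1.0, default=0.86)


# boolean pain-answer triples consistent with each typicality category
_TRIPLES = {
    Typicality.typical: [(True, True, True)],
    Typicality.atypical: [(True, True, False), (True, False, True), (False, True, True)],
    Typicality.non_anginal: [
        (False, False, False),
        (True, False, False),
        (False, True, False),
        (False, False, True),
    ],
}
_TYP_ORDER = (Typicality.typical, Typicality.atypical, Typicality.non_anginal)


def generate_cohort(
    config: CohortGenConfig, seed: Optional[int] = None
) -> list[PatientPresentation]:
    """Draw ``config.n`` independent synthetic presentations.

    Ages are truncated-normal on the validity range and rounded to whole
    years; all binary fields are Bernoulli; pain answers are drawn uniformly
    among the triples consistent with a typicality category sampled from
    ``typicality_probs``. Reproducible from ``seed`` (default ``config.seed``).
    """
    rng = _stage_rng(config.seed if seed is None else seed, "cohort")
    n = config.n
    a = (AGE_MIN - config.age_mean) / config.age_sd
    b = (AGE_MAX - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    ages = np.clip(np.rint(ages).astype(int), AGE_MIN, AGE_MAX)
    male = rng.random(n) < config.p_male
    smoker = rng.random(n) < config.p_smoker
    diabetes = rng.random(n) < config.p_diabetes
    hyperlip = rng.random(n) < config.p_hyperlipidaemia
    ecg = rng.random(n) < config.p_ecg_abnormal
    typ_idx = rng.choice(3, size=n, p=list(config.typicality_probs))
    triple_pick = rng.random(n)  # uniform selector within the category
    med_draws = {
        MedClass.antiplatelet: rng.random(n) < config.p_baseline_antiplatelet,
        MedClass.beta_blocker: rng.random(n) < config.p_baseline_beta_blocker,
        MedClass.statin: rng.random(n) < config.p_baseline_statin,
    }

    cohort = []
    for i in range(n):
        typ = _TYP_ORDER[typ_idx[i]]
        options = _TRIPLES[typ]
        constricting, exertional, relieved = options[int(triple_pick[i] * len(options))]
        cohort.append(
            PatientPresentation(
                patient_id=f"S{i:06d}",
                age=int(ages[i]),
                sex=Sex.male if male[i] else Sex.female,
                smoker=bool(smoker[i]),
                diabetes=bool(diabetes[i]),
                hyperlipidaemia=bool(hyperlip[i]),
                ecg_abnormal=bool(ecg[i]),
                pain_constricting=constricting,
                pain_exertional=exertional,
                pain_relieved_by_rest_or_gtn=relieved,
                baseline_med_classes=frozenset(
                    cls for cls, draws in med_draws.items() if draws[i]
                ),
                group=config.group,
                site=config.site,
            )
        )
    return cohort


_DONE_MODALITY = {
    Investigation.ct_calcium_scoring: InvestigationDone.ct_calcium_scoring,
    Investigation.functional_imaging: InvestigationDone.functional_imaging,
    Investigation.invasive_angiography: InvestigationDone.invasive_angiography,
}


def simulate_pathway(
    cohort: Sequence[PatientPresentation],
    recommendations: Sequence[Recommendation],
    model: AdherenceModel,
    seed: int,
) -> list[FollowUpOutcome]:
    """Simulate six-month outcomes for a matched cohort/recommendation list.

    An investigation happens with ``p_follow_investigation_recommended`` when
    one was recommended (the recommended modality is the one done) and with
    ``p_investigate_when_not_recommended`` otherwise (recorded as ``other``).
    Each recommended medication class not already at baseline is adopted
    independently with ``p_follow_medication``; baseline classes persist.
    """
    if len(cohort) != len(recommendations):
        raise LinkageError(
            f"cohort has {len(cohort)} patients but {len(recommendations)} recommendations"
        )
    rng = _stage_rng(seed, "pathway")
    outcomes = []
    for patient, rec in zip(cohort, recommendations):
        if patient.patient_id != rec.patient_id:
            raise LinkageError(
                f"patient order mismatch: {patient.patient_id!r} vs {rec.patient_id!r}"
            )
        done: set[InvestigationDone] = set()
        if rec.investigation is not Investigation.none:
            if rng.random() < model.p_follow_investigation_recommended:
                done.add(_DONE_MODALITY[rec.investigation])
        else:
            if rng.random() < model.p_investigate_when_not_recommended:
                done.add(InvestigationDone.other)
        meds = set(patient.baseline_med_classes)
        for cls in sorted(rec.recommended_med_classes, key=lambda c: c.value):
            if cls not in meds and rng.random() < model.p_follow_medication:
                meds.add(cls)
        outcomes.append(
            FollowUpOutcome(
                patient_id=patient.patient_id,
                investigations_done=frozenset(done),
                followup_med_classes=frozenset(meds),
            )
        )
    return outcomes


@dataclass(frozen=True)
class StudyData:
    """End-to-end output of one simulated study arm."""

    cohort: list[PatientPresentation]
    recommendations: list[Recommendation]
    outcomes: list[FollowUpOutcome]
    concordance: ConcordanceSummary
    medication: MedDeltaSummary


def run_study(
    gen_config: CohortGenConfig,
    adherence: AdherenceModel,
    guideline: GuidelineConfig,
    seed: Optional[int] = None,
) -> StudyData:
    """generate -> recommend -> simulate -> evaluate, reproducible from one seed."""
    seed = gen_config.seed if seed is None else seed
    cohort = generate_cohort(gen_config, seed)
    use_rng = _stage_rng(seed, "cdss_use")
    cohort = [
        p.model_copy(update={"cdss_used": bool(use_rng.random() < adherence.p_cdss_used)})
        for p in cohort
    ]
    recommendations = run_cdss_batch(cohort, guideline)
    outcomes = simulate_pathway(cohort, recommendations, adherence, seed)
    label = gen_config.group.value
    return StudyData(
        cohort=cohort,
        recommendations=recommendations,
        outcomes=outcomes,
        concordance=investigation_concordance(recommendations, outcomes, group=label),
        medication=medication_delta_summary(cohort, recommendations, outcomes, group=label),
    )


def concordance_records_from_counts(
    n_recommended: int,
    n_recommended_done: int,
    n_not_recommended: int,
    n_not_recommended_done: int,
    *,
    prefix: str = "F",
) -> tuple[list[Recommendation], list[FollowUpOutcome]]:
    """Build a minimal recommendation/outcome fixture realising a 2x2 audit table.

    Useful for reconstructing a published concordance table from its printed
    counts: ``n_recommended_done`` of the ``n_recommended`` patients with an
    investigation recommended had one, and ``n_not_recommended_done`` of the
    ``n_not_recommended`` without a recommendation had one anyway.
    """
    if not (0 <= n_recommended_done <= n_recommended):
        raise ValueError("n_recommended_done outside [0, n_recommended]")
    if not (0 <= n_not_recommended_done <= n_not_recommended):
        raise ValueError("n_not_recommended_done outside [0, n_not_recommended]")
    recs, outcomes = [], []
    idx = 0
    for recommended, done, count in (
        (True, True, n_recommended_done),
        (True, False, n_recommended - n_recommended_done),
        (False, True, n_not_recommended_done),
        (False, False, n_not_recommended - n_not_recommended_done),
    ):
        for _ in range(count):
            pid = f"{prefix}{idx:05d}"
            idx += 1
            recs.append(
                Recommendation(
                    patient_id=pid,
                    typicality=Typicality.atypical if recommended else Typicality.non_anginal,
                    risk_level=RiskLevel.low,
                    ptp=45.0 if recommended else 5.0,
                    investigation=Investigation.functional_imaging
                    if recommended
                    else Investigation.none,
                )
            )
            outcomes.append(
                FollowUpOutcome(
                    patient_id=pid,
                    investigations_done=frozenset(
                        {InvestigationDone.functional_imaging} if done else set()
                    ),
                )
            )
    return recs, outcomes


def med_delta_records_from_counts(
    n_increased: int,
    n_decreased: int,
    n_unchanged: int,
    n_not_recommended_increase: int = 0,
    *,
    prefix: str = "M",
) -> tuple[list[PatientPresentation], list[Recommendation], list[FollowUpOutcome]]:
    """Fixture realising a published medication-change breakdown.

    The first three counts are patients recommended an increase in the number
    of classes whose six-month count went up, down, or stayed equal; the
    remainder are patients whose recommendation did not exceed baseline.
    """
    patients, recs, outcomes = [], [], []
    idx = 0
    followups = {
        "increase": frozenset({MedClass.statin, MedClass.antiplatelet}),
        "decrease": frozenset(),
        "unchanged": frozenset({MedClass.antiplatelet}),  # swap: equal count
        "excluded": frozenset({MedClass.statin}),
    }
    for kind, count in (
        ("increase", n_increased),
        ("decrease", n_decreased),
        ("unchanged", n_unchanged),
        ("excluded", n_not_recommended_increase),
    ):
        for _ in range(count):
            pid = f"{prefix}{idx:05d}"
            idx += 1
            baseline = frozenset({MedClass.statin})
            recommended = (
                baseline
                if kind == "excluded"
                else frozenset({MedClass.statin, MedClass.antiplatelet, MedClass.beta_blocker})
            )
            patients.append(
                PatientPresentation(
                    patient_id=pid,
                    age=60,
                    sex=Sex.male,
                    smoker=False,
                    diabetes=False,
                    hyperlipidaemia=True,
                    ecg_abnormal=False,
                    pain_constricting=True,
                    pain_exertional=True,
                    pain_relieved_by_rest_or_gtn=False,
                    baseline_med_classes=baseline,
                    group=Group.before,
                )
            )
            recs.append(
                Recommendation(
                    patient_id=pid,
                    typicality=Typicality.atypical,
                    risk_level=RiskLevel.high,
                    ptp=79.0,
                    investigation=Investigation.invasive_angiography,
                    recommended_med_classes=recommended,
                )
            )
            outcomes.append(
                FollowUpOutcome(patient_id=pid, followup_med_classes=followups[kind])
            )
    return patients, recs, outcomes
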