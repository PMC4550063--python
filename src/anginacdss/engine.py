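"""The decision logic: pain typicality, risk level, PTP lookup, recommendations.

The pipeline for one patient is

    classify_pain -> stratify_risk -> lookup_ptp -> recommend_investigation
                                                 -> recommend_medications

Chest pain is classified from three yes/no features — constricting quality,
precipitation by exertion, relief by rest or glyceryl trinitrate (GTN) —
as *typical* (all three), *atypical* (exactly two) or *non-anginal* (at most
one). Risk level is *high* if any risk-factor flag is present. The pre-test
probability (PTP) of coronary artery disease is then read from the guideline
table by (sex, age band, typicality, risk level), and the PTP selects an
investigation band and a medication rule. PTPs strictly above the panel
threshold (default 90%) always map to invasive angiography, reflecting the
expert-panel rule for the region the guideline bands do not cover.

Every function here is pure and deterministic; guideline numbers come only
from the :class:`~anginacdss.model.GuidelineConfig` passed in.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Optional, Sequence

from .model import (
    GuidelineConfig,
    Investigation,
    MedClass,
    PatientPresentation,
    Recommendation,
    RiskLevel,
    Sex,
    Typicality,
)

__all__ = [
    "classify_pain",
    "stratify_risk",
    "lookup_ptp",
    "recommend_investigation",
    "recommend_medications",
    "run_cdss",
    "run_cdss_batch",
]


def classify_pain(constricting: bool, exertional: bool, relieved: bool) -> Typicality:
    """Classify chest pain from the three anginal features.

    All three present -> typical angina; exactly two -> atypical angina;
    one or none -> non-anginal pain. Total over all 8 combinations.
    """
    n = int(constricting) + int(exertional) + int(relieved)
    if n == 3:
        return Typicality.typical
    if n == 2:
        return Typicality.atypical
    return Typicality.non_anginal


def stratify_risk(
    smoker: bool,
    diabetes: bool,
    hyperlipidaemia: bool,
    ecg_abnormal: bool,
    *,
    ecg_counts: bool = True,
) -> RiskLevel:
    """High risk iff any risk-factor flag is set, else low.

    ``ecg_counts`` controls whether an abnormal resting ECG counts as a
    risk factor (the packaged default says it does; it is configurable
    because guideline practice varies on this point).
    """
    flags = smoker or diabetes or hyperlipidaemia or (ecg_counts and ecg_abnormal)
    return RiskLevel.high if flags else RiskLevel.low


def lookup_ptp(
    age: int,
    sex: Sex,
    typicality: Typicality,
    risk_level: RiskLevel,
    config: GuidelineConfig,
) -> float:
    """Pre-test probability (%) from the guideline table.

    Ages below the first band edge clamp to the first band; at or above the
    last edge, to the last band.
    """
    band = bisect_right(config.age_band_edges, age)
    return config.ptp_table[(Sex(sex), band, Typicality(typicality), RiskLevel(risk_level))]


def recommend_investigation(ptp: float, config: GuidelineConfig) -> Investigation:
    """Investigation for a PTP: the panel angiography rule strictly above the
    threshold, otherwise the unique guideline band containing the PTP.

    Bands are half-open [lo, hi) with the top band closed at 100, so a PTP
    exactly at the threshold falls in the guideline band below it.
    """
    if not 0.0 <= ptp <= 100.0:
        raise ValueError(f"PTP {ptp} outside [0, 100]")
    if ptp > config.panel_threshold:
        return Investigation.invasive_angiography
    _lo, _hi, investigation = config.investigation_bands[config.band_index(ptp)]
    return investigation


def recommend_medications(
    typicality: Typicality, ptp: float, config: GuidelineConfig
) -> frozenset[MedClass]:
    """Recommended secondary-prevention classes (at most three), from the
    rule table keyed by (typicality, PTP band)."""
    if not 0.0 <= ptp <= 100.0:
        raise ValueError(f"PTP {ptp} outside [0, 100]")
    return config.medication_rules[(Typicality(typicality), config.band_index(ptp))]


def run_cdss(
    patient: PatientPresentation,
    config: GuidelineConfig,
    *,
    typicality_override: Optional[Typicality] = None,
) -> Recommendation:
    """Full decision pipeline for one patient.

    ``typicality_override`` substitutes a clinician-entered pain category for
    the computed one (data entry in practice does not always follow the three
    questions); the default is always the computed classification.
    """
    typicality = (
        Typicality(typicality_override)
        if typicality_override is not None
        else classify_pain(
            patient.pain_constricting,
            patient.pain_exertional,
            patient.pain_relieved_by_rest_or_gtn,
        )
    )
    risk = stratify_risk(
        patient.smoker,
        patient.diabetes,
        patient.hyperlipidaemia,
        patient.ecg_abnormal,
        ecg_counts=config.ecg_counts_as_risk_factor,
    )
    ptp = lookup_ptp(patient.age, patient.sex, typicality, risk, config)
    return Recommendation(
        patient_id=patient.patient_id,
        typicality=typicality,
        risk_level=risk,
        ptp=ptp,
        investigation=recommend_investigation(ptp, config),
        recommended_med_classes=recommend_medications(typicality, ptp, config),
    )


def run_cdss_batch(
    cohort: Sequence[PatientPresentation], config: GuidelineConfig
) -> list[Recommendation]:
    """Apply :func:`run_cdss` to every patient, preserving order."""
    return [run_cdss(p, config) for p in cohort]
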