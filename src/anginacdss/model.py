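"""Domain types for the chest-pain clinic decision-support tool.

The records model a single chest-pain clinic attendance (demographics,
cardiovascular risk factors, resting ECG, the three anginal-pain questions,
and secondary-prevention medication classes current at the clinic date), the
six-month follow-up (cardiac investigations performed, medication classes
current), and the decision-support output for one patient.

Guideline content — the pre-test-probability (PTP) table, the PTP bands that
map to an investigation, and the medication rule table — is *data*, not code:
it lives in :class:`GuidelineConfig`, loaded from an editable YAML file. The
engine enforces only structural invariants (band partition, table totality,
risk/typicality monotonicity) and is agnostic to the numbers.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Sex(str, Enum):
    male = "male"
    female = "female"


class Group(str, Enum):
    """Study arm: seen before or after the clinic received the intervention."""

    before = "before"
    after = "after"


class Typicality(str, Enum):
    """Three-level chest-pain classification from the three anginal features."""

    typical = "typical"
    atypical = "atypical"
    non_anginal = "non_anginal"


class RiskLevel(str, Enum):
    low = "low"
    high = "high"


class MedClass(str, Enum):
    """The three secondary-prevention drug classes the engine may recommend."""

    antiplatelet = "antiplatelet"
    beta_blocker = "beta_blocker"
    statin = "statin"


class Investigation(str, Enum):
    """Diagnostic investigation a PTP band maps to (``none`` = no further test)."""

    none = "none"
    ct_calcium_scoring = "ct_calcium_scoring"
    functional_imaging = "functional_imaging"
    invasive_angiography = "invasive_angiography"


class InvestigationDone(str, Enum):
    """Qualifying cardiac investigations observable at six-month follow-up."""

    ct_calcium_scoring = "ct_calcium_scoring"
    ct_angiography = "ct_angiography"
    functional_imaging = "functional_imaging"
    invasive_angiography = "invasive_angiography"
    other = "other"


#: Declared validity range for patient age at presentation, years.
AGE_MIN, AGE_MAX = 18, 120


class PatientPresentation(BaseModel):
    """One clinic attendance as entered on the data-entry form."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    age: int = Field(ge=AGE_MIN, le=AGE_MAX)
    sex: Sex
    smoker: bool
    diabetes: bool
    hyperlipidaemia: bool
    ecg_abnormal: bool
    pain_constricting: bool
    pain_exertional: bool
    pain_relieved_by_rest_or_gtn: bool
    baseline_med_classes: frozenset[MedClass] = frozenset()
    group: Group
    site: str = ""
    cdss_used: bool = False


class FollowUpOutcome(BaseModel):
    """Investigations performed and medication classes current at six months."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    investigations_done: frozenset[InvestigationDone] = frozenset()
    followup_med_classes: frozenset[MedClass] = frozenset()


class Recommendation(BaseModel):
    """Decision-support output for one patient.

    ``clinician_agrees`` / ``disagreement_reason`` carry the structured
    agreement prompt shown after the recommendation; they are never computed.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    typicality: Typicality
    risk_level: RiskLevel
    ptp: float = Field(ge=0.0, le=100.0)
    investigation: Investigation
    recommended_med_classes: frozenset[MedClass] = frozenset()
    clinician_agrees: Optional[bool] = None
    disagreement_reason: Optional[str] = None

    @model_validator(mode="after")
    def _at_most_three_classes(self) -> "Recommendation":
        if len(self.recommended_med_classes) > 3:  # pragma: no cover - frozenset of 3-enum
            raise ValueError("at most three medication classes may be recommended")
        return self


class GuidelineConfigError(ValueError):
    """A guideline config violates a structural invariant (caught at load time)."""


def _band_of(ptp: float, bands: tuple[tuple[float, float, Investigation], ...]) -> int:
    """Index of the half-open band [lo, hi) containing ``ptp``; top band closed."""
    for i, (lo, hi, _inv) in enumerate(bands):
        if lo <= ptp < hi:
            return i
    last_lo, last_hi, _ = bands[-1]
    if ptp == last_hi:
        return len(bands) - 1
    raise GuidelineConfigError(f"no investigation band contains PTP={ptp}")


class GuidelineConfig(BaseModel):
    """Guideline lookup tables plus the expert-panel angiography threshold.

    ``ptp_table`` maps ``(sex, age-band index, typicality, risk level)`` to a
    pre-test probability in percent. Age bands are defined by the interior
    cut-points ``age_band_edges``: ``len(edges) + 1`` bands, ages below the
    first edge clamp to band 0, at or above the last edge to the last band.

    ``investigation_bands`` partition [0, 100] as half-open ``[lo, hi)``
    intervals with the top band closed at 100. ``medication_rules`` is keyed by
    ``(typicality, investigation-band index)`` and must be total.
    """

    model_config = ConfigDict(frozen=True)

    age_band_edges: tuple[int, ...]
    ptp_table: dict[tuple[Sex, int, Typicality, RiskLevel], float]
    investigation_bands: tuple[tuple[float, float, Investigation], ...]
    medication_rules: dict[tuple[Typicality, int], frozenset[MedClass]]
    panel_threshold: float = 90.0
    ecg_counts_as_risk_factor: bool = True

    @property
    def n_age_bands(self) -> int:
        return len(self.age_band_edges) + 1

    def band_index(self, ptp: float) -> int:
        return _band_of(ptp, self.investigation_bands)

    @model_validator(mode="after")
    def _check_invariants(self) -> "GuidelineConfig":
        if list(self.age_band_edges) != sorted(set(self.age_band_edges)):
            raise GuidelineConfigError(
                f"age_band_edges must be strictly increasing: {self.age_band_edges}"
            )

        # investigation bands partition [0, 100] exactly
        bands = self.investigation_bands
        if not bands:
            raise GuidelineConfigError("investigation_bands is empty")
        if bands[0][0] != 0.0:
            raise GuidelineConfigError(
                f"first investigation band starts at {bands[0][0]}, expected 0"
            )
        if bands[-1][1] != 100.0:
            raise GuidelineConfigError(
                f"last investigation band ends at {bands[-1][1]}, expected 100"
            )
        for (lo1, hi1, _), (lo2, hi2, _) in zip(bands, bands[1:]):
            if hi1 < lo2:
                raise GuidelineConfigError(
                    f"gap between investigation bands [{lo1},{hi1}) and [{lo2},{hi2})"
                )
            if hi1 > lo2:
                raise GuidelineConfigError(
                    f"overlap between investigation bands [{lo1},{hi1}) and [{lo2},{hi2})"
                )
        for lo, hi, _ in bands:
            if not lo < hi:
                raise GuidelineConfigError(f"degenerate investigation band [{lo},{hi})")

        # PTP table totality
        missing = [
            (sex, band, typ, risk)
            for sex in Sex
            for band in range(self.n_age_bands)
            for typ in Typicality
            for risk in RiskLevel
            if (sex, band, typ, risk) not in self.ptp_table
        ]
        if missing:
            raise GuidelineConfigError(f"ptp_table is missing cells: {missing[:5]}")
        for key, value in self.ptp_table.items():
            if not 0.0 <= value <= 100.0:
                raise GuidelineConfigError(f"ptp_table cell {key} = {value} outside [0,100]")

        # risk monotonicity: high-risk PTP >= low-risk PTP
        bad_risk = [
            (sex, band, typ)
            for sex in Sex
            for band in range(self.n_age_bands)
            for typ in Typicality
            if self.ptp_table[(sex, band, typ, RiskLevel.high)]
            < self.ptp_table[(sex, band, typ, RiskLevel.low)]
        ]
        if bad_risk:
            raise GuidelineConfigError(
                f"ptp_table not monotone in risk level at cells: {bad_risk}"
            )

        # typicality monotonicity: typical >= atypical >= non-anginal
        order = (Typicality.non_anginal, Typicality.atypical, Typicality.typical)
        bad_typ = [
            (sex, band, risk, lower.value, higher.value)
            for sex in Sex
            for band in range(self.n_age_bands)
            for risk in RiskLevel
            for lower, higher in zip(order, order[1:])
            if self.ptp_table[(sex, band, higher, risk)]
            < self.ptp_table[(sex, band, lower, risk)]
        ]
        if bad_typ:
            raise GuidelineConfigError(
                f"ptp_table not monotone in typicality at cells: {bad_typ}"
            )

        # medication rule totality and cardinality
        missing_rules = [
            (typ, band)
            for typ in Typicality
            for band in range(len(bands))
            if (typ, band) not in self.medication_rules
        ]
        if missing_rules:
            raise GuidelineConfigError(f"medication_rules is missing keys: {missing_rules}")

        if not 0.0 <= self.panel_threshold <= 100.0:
            raise GuidelineConfigError(
                f"panel_threshold {self.panel_threshold} outside [0,100]"
            )
        return self
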