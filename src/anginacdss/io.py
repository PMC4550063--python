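"""Readers and writers for cohort files, recommendation files and guideline configs.

File conventions
----------------
Cohort files are UTF-8 CSV with a header row and the columns

``patient_id, age, sex, smoker, diabetes, hyperlipidaemia, ecg_abnormal,
pain_constricting, pain_exertional, pain_relieved_by_rest_or_gtn,
baseline_meds, group, site, cdss_used, investigations_6m, meds_6m``

Booleans are ``0``/``1``; categorical values are lower-case tokens;
multi-valued fields are semicolon-separated with the empty string meaning the
empty set. A patient with no six-month follow-up linkage carries the literal
token ``na`` in *both* ``investigations_6m`` and ``meds_6m`` (``na`` in only
one of the two is a row error). Such patients are excluded from concordance
denominators downstream.

Guideline configs are YAML; see the packaged default
``data/guideline_nice_cg95.yaml`` for the documented schema. Structural
invariants (band partition, table totality, monotonicity) are enforced at
load time by :class:`~anginacdss.model.GuidelineConfig`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .model import (
    FollowUpOutcome,
    GuidelineConfig,
    GuidelineConfigError,
    Investigation,
    InvestigationDone,
    MedClass,
    PatientPresentation,
    Recommendation,
)

__all__ = [
    "COHORT_COLUMNS",
    "CohortSchemaError",
    "CohortRecord",
    "read_cohort",
    "write_cohort",
    "read_recommendations",
    "write_recommendations",
    "load_guideline_config",
    "default_guideline_path",
    "make_guideline_config",
]

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "smoker",
    "diabetes",
    "hyperlipidaemia",
    "ecg_abnormal",
    "pain_constricting",
    "pain_exertional",
    "pain_relieved_by_rest_or_gtn",
    "baseline_meds",
    "group",
    "site",
    "cdss_used",
    "investigations_6m",
    "meds_6m",
]

RECOMMENDATION_COLUMNS = [
    "patient_id",
    "typicality",
    "risk_level",
    "ptp",
    "investigation",
    "recommended_meds",
    "clinician_agrees",
    "disagreement_reason",
]

#: Follow-up fields carrying this token (in both columns) mark a patient
#: with no six-month linkage.
NA_TOKEN = "na"

CohortRecord = tuple[PatientPresentation, Optional[FollowUpOutcome]]


class CohortSchemaError(ValueError):
    """A cohort file does not conform to the documented schema."""


def _parse_bool(value: str, column: str, row: int) -> bool:
    if value == "1":
        return True
    if value == "0":
        return False
    raise CohortSchemaError(f"row {row}: column '{column}' must be 0/1, got {value!r}")


def _parse_set(value: str) -> list[str]:
    return [tok for tok in value.split(";") if tok]


def _fmt_bool(value: bool) -> str:
    return "1" if value else "0"


def _fmt_set(values: Sequence[str]) -> str:
    return ";".join(sorted(values))


def read_cohort(path: Union[str, Path]) -> list[CohortRecord]:
    """Read a cohort CSV into validated (presentation, optional follow-up) pairs.

    Row order is preserved. Raises :class:`CohortSchemaError` naming the column
    for a missing mandatory column, or the 1-based data row for a value that
    fails validation.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[CohortRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        try:
            patient = PatientPresentation(
                patient_id=data["patient_id"],
                age=int(data["age"]),
                sex=data["sex"],
                smoker=_parse_bool(data["smoker"], "smoker", i),
                diabetes=_parse_bool(data["diabetes"], "diabetes", i),
                hyperlipidaemia=_parse_bool(data["hyperlipidaemia"], "hyperlipidaemia", i),
                ecg_abnormal=_parse_bool(data["ecg_abnormal"], "ecg_abnormal", i),
                pain_constricting=_parse_bool(data["pain_constricting"], "pain_constricting", i),
                pain_exertional=_parse_bool(data["pain_exertional"], "pain_exertional", i),
                pain_relieved_by_rest_or_gtn=_parse_bool(
                    data["pain_relieved_by_rest_or_gtn"], "pain_relieved_by_rest_or_gtn", i
                ),
                baseline_med_classes=frozenset(
                    MedClass(tok) for tok in _parse_set(data["baseline_meds"])
                ),
                group=data["group"],
                site=data["site"],
                cdss_used=_parse_bool(data["cdss_used"], "cdss_used", i),
            )
            inv_raw, med_raw = data["investigations_6m"], data["meds_6m"]
            if inv_raw == NA_TOKEN or med_raw == NA_TOKEN:
                if not (inv_raw == NA_TOKEN and med_raw == NA_TOKEN):
                    raise CohortSchemaError(
                        f"row {i}: '{NA_TOKEN}' must appear in both follow-up "
                        "columns or neither"
                    )
                outcome: Optional[FollowUpOutcome] = None
            else:
                outcome = FollowUpOutcome(
                    patient_id=patient.patient_id,
                    investigations_done=frozenset(
                        InvestigationDone(tok) for tok in _parse_set(inv_raw)
                    ),
                    followup_med_classes=frozenset(
                        MedClass(tok) for tok in _parse_set(med_raw)
                    ),
                )
        except CohortSchemaError:
            raise
        except (ValueError, ValidationError) as exc:
            raise CohortSchemaError(f"row {i}: {exc}") from exc
        records.append((patient, outcome))
    return records


def write_cohort(path: Union[str, Path], records: Sequence[CohortRecord]) -> None:
    """Write (presentation, optional follow-up) pairs to the documented CSV schema."""
    rows = []
    for patient, outcome in records:
        rows.append(
            {
                "patient_id": patient.patient_id,
                "age": patient.age,
                "sex": patient.sex.value,
                "smoker": _fmt_bool(patient.smoker),
                "diabetes": _fmt_bool(patient.diabetes),
                "hyperlipidaemia": _fmt_bool(patient.hyperlipidaemia),
                "ecg_abnormal": _fmt_bool(patient.ecg_abnormal),
                "pain_constricting": _fmt_bool(patient.pain_constricting),
                "pain_exertional": _fmt_bool(patient.pain_exertional),
                "pain_relieved_by_rest_or_gtn": _fmt_bool(patient.pain_relieved_by_rest_or_gtn),
                "baseline_meds": _fmt_set([m.value for m in patient.baseline_med_classes]),
                "group": patient.group.value,
                "site": patient.site,
                "cdss_used": _fmt_bool(patient.cdss_used),
                "investigations_6m": NA_TOKEN
                if outcome is None
                else _fmt_set([v.value for v in outcome.investigations_done]),
                "meds_6m": NA_TOKEN
                if outcome is None
                else _fmt_set([m.value for m in outcome.followup_med_classes]),
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def write_recommendations(path: Union[str, Path], recs: Sequence[Recommendation]) -> None:
    rows = []
    for rec in recs:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "typicality": rec.typicality.value,
                "risk_level": rec.risk_level.value,
                "ptp": rec.ptp,
                "investigation": rec.investigation.value,
                "recommended_meds": _fmt_set([m.value for m in rec.recommended_med_classes]),
                "clinician_agrees": ""
                if rec.clinician_agrees is None
                else _fmt_bool(rec.clinician_agrees),
                "disagreement_reason": rec.disagreement_reason or "",
            }
        )
    pd.DataFrame(rows, columns=RECOMMENDATION_COLUMNS).to_csv(path, index=False)


def read_recommendations(path: Union[str, Path]) -> list[Recommendation]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECOMMENDATION_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    recs = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        try:
            recs.append(
                Recommendation(
                    patient_id=data["patient_id"],
                    typicality=data["typicality"],
                    risk_level=data["risk_level"],
                    ptp=float(data["ptp"]),
                    investigation=data["investigation"],
                    recommended_med_classes=frozenset(
                        MedClass(tok) for tok in _parse_set(data["recommended_meds"])
                    ),
                    clinician_agrees=None
                    if data["clinician_agrees"] == ""
                    else _parse_bool(data["clinician_agrees"], "clinician_agrees", i),
                    disagreement_reason=data["disagreement_reason"] or None,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise CohortSchemaError(f"row {i}: {exc}") from exc
    return recs


def default_guideline_path() -> Path:
    """Path of the packaged default guideline config."""
    return Path(resources.files("anginacdss") / "data" / "guideline_nice_cg95.yaml")


def make_guideline_config(**fields) -> GuidelineConfig:
    """Construct a :class:`GuidelineConfig`, converting pydantic validation
    failures into :class:`GuidelineConfigError`."""
    try:
        return GuidelineConfig(**fields)
    except ValidationError as exc:
        raise GuidelineConfigError(str(exc)) from exc


def load_guideline_config(path: Union[str, Path, None] = None) -> GuidelineConfig:
    """Load and validate a guideline config (the packaged default if ``path`` is None).

    All structural invariants are enforced here, at load time; violations raise
    :class:`GuidelineConfigError` describing the offending cells or intervals.
    """
    if path is None:
        path = default_guideline_path()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise GuidelineConfigError(f"config {path} is not a mapping")
    for section in ("age_bands", "ptp_table", "investigation_bands", "medication_rules"):
        if section not in raw:
            raise GuidelineConfigError(f"config {path} is missing section '{section}'")

    edges = tuple(raw["age_bands"])
    n_bands = len(edges) + 1

    ptp_table: dict = {}
    for sex_key, by_typ in raw["ptp_table"].items():
        for typ_key, by_risk in by_typ.items():
            for risk_key, values in by_risk.items():
                if len(values) != n_bands:
                    raise GuidelineConfigError(
                        f"ptp_table[{sex_key}][{typ_key}][{risk_key}] has "
                        f"{len(values)} values, expected {n_bands} age bands"
                    )
                for band, value in enumerate(values):
                    ptp_table[(sex_key, band, typ_key, risk_key)] = float(value)

    bands = tuple(
        (float(b["lo"]), float(b["hi"]), b["investigation"])
        for b in raw["investigation_bands"]
    )

    med_rules: dict = {}
    for typ_key, per_band in raw["medication_rules"].items():
        if len(per_band) != len(bands):
            raise GuidelineConfigError(
                f"medication_rules[{typ_key}] has {len(per_band)} entries, "
                f"expected {len(bands)} investigation bands"
            )
        for band, classes in enumerate(per_band):
            med_rules[(typ_key, band)] = frozenset(MedClass(c) for c in classes)

    return make_guideline_config(
        age_band_edges=edges,
        ptp_table=ptp_table,
        investigation_bands=bands,
        medication_rules=med_rules,
        panel_threshold=float(raw.get("panel_threshold", 90)),
        ecg_counts_as_risk_factor=bool(raw.get("ecg_counts_as_risk_factor", True)),
    )
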