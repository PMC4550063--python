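"""Concordance statistics, binomial confidence intervals and sample size.

The audit question is whether observed management *followed* the
recommendation: a patient counts as followed iff an investigation was
recommended and at least one qualifying cardiac investigation was done within
six months, or none was recommended and none was done. Proportions are
reported with Wald (normal-approximation) 95% confidence intervals,

    p-hat +/- z * sqrt(p-hat (1 - p-hat) / n),

on the percent scale. All interval arithmetic is done on the exact
proportion; rounding to integer percent (half up, halves away from zero) is a
separate presentation step, so re-rounding never feeds back into the numbers.

Medication change is count-based: the number of secondary-prevention classes
at follow-up versus baseline (an exchange of one class for another is
*unchanged*); a set-based variant is available behind a flag.

The sample-size routine is the standard two-sided two-proportion formula with
pooled variance under the null, optionally with the Fleiss continuity
correction n' = (n/4) * (1 + sqrt(1 + 4 / (n * |p1 - p2|)))^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .model import FollowUpOutcome, Investigation, PatientPresentation, Recommendation

__all__ = [
    "round_half_up",
    "wald_ci",
    "two_proportion_diff_ci",
    "ConcordanceSummary",
    "investigation_concordance",
    "MedDelta",
    "medication_delta",
    "MedDeltaSummary",
    "medication_delta_summary",
    "sample_size_two_proportions",
    "simulate_two_proportion_power",
    "LinkageError",
]


class LinkageError(ValueError):
    """Recommendations and follow-up outcomes could not be matched by patient id."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (presentation rule)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def wald_ci(
    k: int, n: int, level: float = 0.95, *, clamp: bool = True
) -> tuple[float, float]:
    """Wald binomial confidence interval for k successes in n trials, in percent.

    Bounds are clamped to [0, 100] unless ``clamp=False`` (the raw normal
    approximation can cross zero for small proportions). Raises ``ValueError``
    for n = 0 (undefined proportion) or k outside [0, n].
    """
    if n <= 0:
        raise ValueError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0 < level < 1:
        raise ValueError(f"confidence level {level} outside (0, 1)")
    p = k / n
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1.0 - p) / n)
    lo, hi = 100.0 * (p - half), 100.0 * (p + half)
    if clamp:
        lo, hi = max(lo, 0.0), min(hi, 100.0)
    return lo, hi


def two_proportion_diff_ci(
    k1: int, n1: int, k2: int, n2: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Difference of two independent proportions with its Wald interval, in percent.

    Returns ``(diff, lo, hi)`` where diff = p1-hat - p2-hat and the interval is
    diff +/- z * sqrt(p1q1/n1 + p2q2/n2). Antisymmetric under swapping the
    two samples.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("proportion undefined for n = 0")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("k outside [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    z = norm.ppf(0.5 + level / 2)
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    diff = 100.0 * (p1 - p2)
    return diff, diff - 100.0 * z * se, diff + 100.0 * z * se


@dataclass(frozen=True)
class ProportionWithCI:
    """A proportion (percent) with its confidence bounds, plus rounded views."""

    k: int
    n: int
    pct: float
    lo: float
    hi: float

    @property
    def rounded(self) -> tuple[int, int, int]:
        return round_half_up(self.pct), round_half_up(self.lo), round_half_up(self.hi)


def _proportion(k: int, n: int, level: float) -> ProportionWithCI:
    lo, hi = wald_ci(k, n, level)
    return ProportionWithCI(k=k, n=n, pct=100.0 * k / n, lo=lo, hi=hi)


@dataclass(frozen=True)
class ConcordanceSummary:
    """Cohort-level agreement of observed investigations with recommendations."""

    group: str
    n_total: int
    n_recommended_investigation: int
    n_recommended_done: int
    n_recommended_none: int
    n_none_but_done: int
    n_followed: int
    followed: ProportionWithCI
    recommended_investigation: ProportionWithCI
    done_when_recommended: ProportionWithCI
    done_when_not_recommended: ProportionWithCI

    def __post_init__(self) -> None:
        if self.n_total != self.n_recommended_investigation + self.n_recommended_none:
            raise ValueError("n_total must equal recommended + not-recommended")
        expected = self.n_recommended_done + (self.n_recommended_none - self.n_none_but_done)
        if self.n_followed != expected:
            raise ValueError("n_followed inconsistent with component counts")

    @classmethod
    def from_counts(
        cls,
        group: str,
        n_recommended: int,
        n_recommended_done: int,
        n_not_recommended: int,
        n_not_recommended_done: int,
        level: float = 0.95,
    ) -> "ConcordanceSummary":
        n_total = n_recommended + n_not_recommended
        n_followed = n_recommended_done + (n_not_recommended - n_not_recommended_done)
        return cls(
            group=group,
            n_total=n_total,
            n_recommended_investigation=n_recommended,
            n_recommended_done=n_recommended_done,
            n_recommended_none=n_not_recommended,
            n_none_but_done=n_not_recommended_done,
            n_followed=n_followed,
            followed=_proportion(n_followed, n_total, level),
            recommended_investigation=_proportion(n_recommended, n_total, level),
            done_when_recommended=_proportion(n_recommended_done, n_recommended, level),
            done_when_not_recommended=_proportion(
                n_not_recommended_done, n_not_recommended, level
            ),
        )


def _outcome_map(
    outcomes: Union[Mapping[str, FollowUpOutcome], Iterable[FollowUpOutcome]]
) -> Mapping[str, FollowUpOutcome]:
    if isinstance(outcomes, Mapping):
        return outcomes
    return {o.patient_id: o for o in outcomes}


def investigation_concordance(
    recommendations: Sequence[Recommendation],
    outcomes: Union[Mapping[str, FollowUpOutcome], Iterable[FollowUpOutcome]],
    *,
    group: str = "",
    level: float = 0.95,
) -> ConcordanceSummary:
    """Tabulate agreement of six-month investigations with the recommendations.

    "Done" means at least one qualifying cardiac investigation of any modality
    was performed within follow-up — the audit is recommended-versus-any-done,
    not modality matching. Every recommendation must have a follow-up outcome
    (patients without linkage are excluded upstream); a missing patient id
    raises :class:`LinkageError`.
    """
    omap = _outcome_map(outcomes)
    n_rec = n_rec_done = n_none = n_none_done = 0
    for rec in recommendations:
        try:
            outcome = omap[rec.patient_id]
        except KeyError:
            raise LinkageError(
                f"no follow-up outcome for patient {rec.patient_id!r}"
            ) from None
        done = len(outcome.investigations_done) > 0
        if rec.investigation is not Investigation.none:
            n_rec += 1
            n_rec_done += done
        else:
            n_none += 1
            n_none_done += done
    return ConcordanceSummary.from_counts(
        group, n_rec, n_rec_done, n_none, n_none_done, level
    )


class MedDelta(str, Enum):
    increase = "increase"
    decrease = "decrease"
    unchanged = "unchanged"


def medication_delta(
    baseline_meds: frozenset,
    followup_meds: frozenset,
    *,
    set_based: bool = False,
) -> MedDelta:
    """Classify the medication change from baseline to six months.

    Default is count-based — the *number* of classes: more -> increase, fewer
    -> decrease, equal -> unchanged (swapping one class for another is
    unchanged). With ``set_based=True``, any added class -> increase, else any
    removed class -> decrease, else unchanged.
    """
    if set_based:
        if followup_meds - baseline_meds:
            return MedDelta.increase
        if baseline_meds - followup_meds:
            return MedDelta.decrease
        return MedDelta.unchanged
    if len(followup_meds) > len(baseline_meds):
        return MedDelta.increase
    if len(followup_meds) < len(baseline_meds):
        return MedDelta.decrease
    return MedDelta.unchanged


@dataclass(frozen=True)
class MedDeltaSummary:
    """Observed medication change among patients recommended an increase."""

    group: str
    n_total: int
    n_recommended_increase: int
    n_increased: int
    n_decreased: int
    n_unchanged: int
    recommended_increase: ProportionWithCI
    increased: ProportionWithCI
    decreased: ProportionWithCI
    unchanged: ProportionWithCI

    def __post_init__(self) -> None:
        if self.n_increased + self.n_decreased + self.n_unchanged != self.n_recommended_increase:
            raise ValueError("delta categories must partition the recommended-increase set")

    @classmethod
    def from_counts(
        cls,
        group: str,
        n_total: int,
        n_increased: int,
        n_decreased: int,
        n_unchanged: int,
        level: float = 0.95,
    ) -> "MedDeltaSummary":
        n_ri = n_increased + n_decreased + n_unchanged
        return cls(
            group=group,
            n_total=n_total,
            n_recommended_increase=n_ri,
            n_increased=n_increased,
            n_decreased=n_decreased,
            n_unchanged=n_unchanged,
            recommended_increase=_proportion(n_ri, n_total, level),
            increased=_proportion(n_increased, n_ri, level),
            decreased=_proportion(n_decreased, n_ri, level),
            unchanged=_proportion(n_unchanged, n_ri, level),
        )


def medication_delta_summary(
    patients: Sequence[PatientPresentation],
    recommendations: Sequence[Recommendation],
    outcomes: Union[Mapping[str, FollowUpOutcome], Iterable[FollowUpOutcome]],
    *,
    group: str = "",
    level: float = 0.95,
    set_based: bool = False,
) -> MedDeltaSummary:
    """Restrict to patients for whom the recommendation would *increase* the
    number of medication classes, and classify what actually happened."""
    omap = _outcome_map(outcomes)
    pmap = {p.patient_id: p for p in patients}
    counts = {MedDelta.increase: 0, MedDelta.decrease: 0, MedDelta.unchanged: 0}
    for rec in recommendations:
        try:
            patient = pmap[rec.patient_id]
            outcome = omap[rec.patient_id]
        except KeyError as exc:
            raise LinkageError(f"no linkage for patient {exc.args[0]!r}") from None
        if len(rec.recommended_med_classes) <= len(patient.baseline_med_classes):
            continue
        delta = medication_delta(
            patient.baseline_med_classes,
            outcome.followup_med_classes,
            set_based=set_based,
        )
        counts[delta] += 1
    return MedDeltaSummary.from_counts(
        group,
        len(recommendations),
        counts[MedDelta.increase],
        counts[MedDelta.decrease],
        counts[MedDelta.unchanged],
        level,
    )


def sample_size_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.90,
    *,
    continuity_correction: bool = True,
) -> int:
    """Per-group n to detect p1 vs p2 with a two-sided pooled z-test.

    Uncorrected closed form:
        n = (z_{a/2} sqrt(2 pbar qbar) + z_b sqrt(p1 q1 + p2 q2))^2 / (p1-p2)^2
    with pbar = (p1+p2)/2. With ``continuity_correction`` (the default), the
    Fleiss adjustment n' = (n/4)(1 + sqrt(1 + 4/(n |p1-p2|)))^2 is applied to
    the unrounded n. The result is rounded up to an integer.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name}={p} must lie strictly in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 == p2: no finite sample size")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie strictly in (0, 1)")
    delta = abs(p1 - p2)
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    pbar = (p1 + p2) / 2.0
    n = (
        z_a * math.sqrt(2.0 * pbar * (1.0 - pbar))
        + z_b * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))
    ) ** 2 / delta**2
    if continuity_correction:
        n = (n / 4.0) * (1.0 + math.sqrt(1.0 + 4.0 / (n * delta))) ** 2
    return math.ceil(n - 1e-12)


def simulate_two_proportion_power(
    p1: float,
    p2: float,
    n_per_group: int,
    alpha: float = 0.05,
    n_reps: int = 20_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo power of the two-sided pooled two-proportion z-test.

    Independent oracle for the closed-form sample size: draws ``n_reps``
    replicate pairs of binomials and returns the rejection rate.
    """
    rng = np.random.default_rng(rng)
    k1 = rng.binomial(n_per_group, p1, size=n_reps)
    k2 = rng.binomial(n_per_group, p2, size=n_reps)
    ph1, ph2 = k1 / n_per_group, k2 / n_per_group
    pooled = (k1 + k2) / (2 * n_per_group)
    se = np.sqrt(pooled * (1 - pooled) * (2 / n_per_group))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (ph1 - ph2) / se, 0.0)
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    return float(np.mean(np.abs(z) > z_crit))
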