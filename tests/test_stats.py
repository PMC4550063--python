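"""Confidence intervals, concordance tabulation, medication deltas, sample size."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.proportion import proportion_confint

from anginacdss import (
    FollowUpOutcome,
    Investigation,
    InvestigationDone,
    LinkageError,
    MedClass,
    MedDelta,
    Recommendation,
    RiskLevel,
    Typicality,
    concordance_records_from_counts,
    investigation_concordance,
    medication_delta,
    round_half_up,
    sample_size_two_proportions,
    simulate_two_proportion_power,
    two_proportion_diff_ci,
    wald_ci,
)
from anginacdss.stats import ConcordanceSummary, MedDeltaSummary


def rounded(ci):
    return tuple(round_half_up(x) for x in ci)


# --- Wald intervals ---------------------------------------------------------


def test_wald_matches_statsmodels_normal_interval():
    """Independent route: statsmodels' normal-approximation interval."""
    for k, n in [(18, 36), (44, 74), (154, 179), (1, 50), (49, 50), (7, 34)]:
        # statsmodels clips the normal interval to [0, 1], as does our default
        lo, hi = wald_ci(k, n)
        sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="normal")
        assert lo == pytest.approx(100 * sm_lo)
        assert hi == pytest.approx(100 * sm_hi)


def test_wald_lower_bound_clamps_at_zero():
    lo, hi = wald_ci(0, 10)
    assert lo == 0.0 and hi == 0.0  # p-hat = 0: degenerate normal interval
    lo, hi = wald_ci(1, 10)
    assert lo == 0.0  # raw bound is negative; clamped
    assert wald_ci(1, 10, clamp=False)[0] < 0.0


def test_wald_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        wald_ci(0, 0)
    with pytest.raises(ValueError):
        wald_ci(5, 4)
    with pytest.raises(ValueError):
        wald_ci(1, 10, level=1.0)


@given(
    st.integers(1, 500).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))),
    st.sampled_from([0.80, 0.90, 0.95, 0.99]),
)
def test_wald_contained_in_range_and_widens_with_level(nk, level):
    n, k = nk
    lo, hi = wald_ci(k, n, level)
    assert 0.0 <= lo <= hi <= 100.0
    lo99, hi99 = wald_ci(k, n, 0.995)
    assert lo99 <= lo and hi99 >= hi


def test_presentation_rounding_is_half_up_including_negatives():
    assert round_half_up(65.5) == 66
    assert round_half_up(65.4999) == 65
    assert round_half_up(-2.5) == -3
    assert round_half_up(-2.4999) == -2


# --- two-proportion difference ----------------------------------------------


def test_diff_ci_is_zero_and_symmetric_for_identical_samples():
    diff, lo, hi = two_proportion_diff_ci(30, 60, 30, 60)
    assert diff == 0.0
    assert lo == pytest.approx(-hi)


@given(
    st.tuples(st.integers(1, 200), st.integers(1, 200)).flatmap(
        lambda ns: st.tuples(
            st.just(ns[0]),
            st.integers(0, ns[0]),
            st.just(ns[1]),
            st.integers(0, ns[1]),
        )
    )
)
def test_diff_ci_antisymmetric_under_group_swap(knkn):
    n1, k1, n2, k2 = knkn
    d1, lo1, hi1 = two_proportion_diff_ci(k1, n1, k2, n2)
    d2, lo2, hi2 = two_proportion_diff_ci(k2, n2, k1, n1)
    assert d1 == pytest.approx(-d2)
    assert lo1 == pytest.approx(-hi2)
    assert hi1 == pytest.approx(-lo2)


def test_diff_ci_rejects_zero_denominator():
    with pytest.raises(ValueError):
        two_proportion_diff_ci(0, 0, 1, 10)


# --- concordance ------------------------------------------------------------


def test_perfect_adherence_gives_full_concordance():
    recs, outs = concordance_records_from_counts(40, 40, 60, 0)
    s = investigation_concordance(recs, outs)
    assert s.n_followed == s.n_total == 100
    assert s.followed.pct == 100.0


def test_summary_count_identities():
    s = ConcordanceSummary.from_counts("g", 36, 18, 70, 10)
    assert s.n_total == s.n_recommended_investigation + s.n_recommended_none
    assert s.n_followed == s.n_recommended_done + (s.n_recommended_none - s.n_none_but_done)


def test_inconsistent_summary_counts_are_rejected():
    good = ConcordanceSummary.from_counts("g", 10, 5, 10, 2)
    bad = {**good.__dict__, "n_followed": good.n_followed + 1}
    with pytest.raises(ValueError):
        ConcordanceSummary(**bad)


def test_unmatched_patient_raises_linkage_error():
    recs, outs = concordance_records_from_counts(2, 1, 2, 0)
    with pytest.raises(LinkageError, match=recs[0].patient_id):
        investigation_concordance(recs, outs[1:])


def _brute_force_concordance(recs, outs):
    """Per-patient oracle loop, independent of the tabulation code."""
    omap = {o.patient_id: o for o in outs}
    followed = 0
    for rec in recs:
        done = len(omap[rec.patient_id].investigations_done) > 0
        recommended = rec.investigation is not Investigation.none
        if (recommended and done) or (not recommended and not done):
            followed += 1
    return followed


@pytest.mark.parametrize("n, seed", [(10, 0), (137, 1), (1000, 2)])
def test_concordance_equals_per_patient_oracle_on_random_cohorts(n, seed):
    rng = np.random.default_rng(seed)
    recs, outs = [], []
    for i in range(n):
        recommended = bool(rng.random() < 0.4)
        done = bool(rng.random() < 0.5)
        recs.append(
            Recommendation(
                patient_id=f"r{i}",
                typicality=Typicality.atypical if recommended else Typicality.non_anginal,
                risk_level=RiskLevel.low,
                ptp=45.0 if recommended else 5.0,
                investigation=Investigation.functional_imaging
                if recommended
                else Investigation.none,
            )
        )
        outs.append(
            FollowUpOutcome(
                patient_id=f"r{i}",
                investigations_done=frozenset(
                    {InvestigationDone.other} if done else set()
                ),
            )
        )
    s = investigation_concordance(recs, outs)
    assert s.n_followed == _brute_force_concordance(recs, outs)
    assert s.n_total == n


# --- medication delta -------------------------------------------------------

S, A, B = MedClass.statin, MedClass.antiplatelet, MedClass.beta_blocker


@pytest.mark.parametrize(
    "baseline, followup, expected",
    [
        (frozenset({S}), frozenset({S, A}), MedDelta.increase),
        (frozenset({S}), frozenset({A}), MedDelta.unchanged),  # swap, count-based
        (frozenset({S, A}), frozenset({A}), MedDelta.decrease),
        (frozenset(), frozenset(), MedDelta.unchanged),
    ],
)
def test_medication_delta_is_count_based(baseline, followup, expected):
    assert medication_delta(baseline, followup) is expected


def test_set_based_variant_counts_a_swap_as_increase():
    assert medication_delta(frozenset({S}), frozenset({A}), set_based=True) is MedDelta.increase


@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 200))
def test_med_delta_summary_partition_invariant(ninc, ndec, nunch, extra):
    n_ri = ninc + ndec + nunch
    if n_ri == 0:
        return  # no recommended-increase patients: proportions undefined
    s = MedDeltaSummary.from_counts("g", n_ri + extra, ninc, ndec, nunch)
    assert s.n_increased + s.n_decreased + s.n_unchanged == s.n_recommended_increase


# --- sample size ------------------------------------------------------------


def test_sample_size_without_correction_matches_closed_form():
    # hand-computed from the pooled-variance formula
    assert sample_size_two_proportions(0.75, 0.85, continuity_correction=False) == 335


def test_sample_size_monotone_in_power():
    ns = [
        sample_size_two_proportions(0.75, 0.85, power=p)
        for p in (0.5, 0.7, 0.8, 0.9, 0.95)
    ]
    assert ns == sorted(ns)


def test_sample_size_rejects_equal_proportions():
    with pytest.raises(ValueError):
        sample_size_two_proportions(0.8, 0.8)
    with pytest.raises(ValueError):
        sample_size_two_proportions(0.0, 0.5)


def test_monte_carlo_power_sanity_at_closed_form_n():
    n = sample_size_two_proportions(0.75, 0.85, continuity_correction=False)
    power = simulate_two_proportion_power(
        0.75, 0.85, n, n_reps=5000, rng=np.random.default_rng(0)
    )
    assert power == pytest.approx(0.90, abs=0.02)
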