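# Methods

## The decision model

The engine is a deterministic rule pipeline over one clinic attendance:

1. **Pain typicality.** Three binary features — constricting character,
   exertional precipitation, relief by rest or GTN — classify the pain as
   typical angina (all three present), atypical angina (exactly two) or
   non-anginal (at most one). The classifier is total over the 8 input
   combinations, with preimage sizes 1 / 3 / 4.
2. **Risk stratification.** *High* iff any flag among smoking, diabetes,
   hyperlipidaemia and (by default) abnormal resting ECG is present,
   otherwise *low*. Whether the ECG counts is a config switch
   (`ecg_counts_as_risk_factor`) because guideline practice is not uniform
   on the point; the packaged default includes it.
3. **Pre-test probability.** A lookup in the guideline table keyed by sex,
   age band, typicality and risk level. The packaged table carries the CG95
   values (Pryor-modified Diamond–Forrester estimates) with age bands <45,
   45–54, 55–64, ≥65; ages outside the covered range clamp to the terminal
   bands. The engine never hard-codes probabilities: the table ships as an
   editable YAML file and only its structure is enforced — totality over the
   key domain, PTP(high risk) ≥ PTP(low risk) within any cell, and
   PTP(typical) ≥ PTP(atypical) ≥ PTP(non-anginal).
4. **Investigation.** PTP bands partition [0, 100] as half-open [lo, hi)
   intervals with the top band closed at 100: <10 % no further
   investigation, 10–29 % CT calcium scoring, 30–60 % functional imaging,
   61–90 % invasive angiography. Strictly above the panel threshold
   (90 %) an expert-panel rule recommends invasive angiography outright; a
   PTP of exactly 90 falls in the ordinary band below, so there is no gap
   at the threshold. Contraindications are out of scope of the engine and
   surface only through the structured clinician-disagreement field.
5. **Medications.** Up to three secondary-prevention classes (antiplatelet,
   statin, beta-blocker) read from a rule table keyed by (typicality, PTP
   band). The original panel's rules were never published, so the packaged
   table is an explicitly **synthetic stand-in**: empty at minimal
   probability, escalating to all three classes at high probability. It is
   data, not code, and is meant to be edited. Baseline medications never
   alter the recommendation; they only enter the downstream change
   classification.

A clinician-entered typicality can override the computed one
(`typicality_override`), defaulting to the computed value; data entry in
live use does not always follow the three questions, and both behaviours
must be testable.

## Concordance and medication-change statistics

A patient's management *followed* the recommendation iff an investigation
was recommended and at least one qualifying cardiac investigation of any
modality was done within six months, or none was recommended and none was
done — recommended-versus-any-done, not modality matching. Patients without
six-month linkage are excluded from every denominator.

Proportions carry Wald (normal-approximation) intervals on the percent
scale, computed from the **exact** proportion and clamped to [0, 100]
(`clamp=False` exposes the raw normal bounds, which can cross zero for
small proportions). Rounding to integer percent — half up, halves away from
zero — is purely presentational and never feeds back into computation. Note
that the alternative convention of computing the interval from an already
rounded point estimate moves a bound by one percentage point in a
non-trivial fraction of small-sample cases; historical audit tables of this
pathway mix the two conventions, so agreement with such tables at integer
precision cannot be perfect under any single rule. This package always uses
the exact-proportion convention.

Medication change is **count-based**: the number of classes at six months
versus baseline (greater → increase, smaller → decrease, equal → unchanged,
so a one-for-one swap is unchanged). A set-based variant is available
behind `set_based=True` but is not the default. The change summary is
restricted to patients whose recommended class count exceeds baseline.

The sample-size routine implements the two-sided two-proportion formula
with pooled variance,

    n = (z_{α/2}·√(2·p̄q̄) + z_β·√(p₁q₁ + p₂q₂))² / (p₁ − p₂)²,

and, by default, the Fleiss continuity correction
n' = (n/4)·(1 + √(1 + 4/(n·|p₁−p₂|)))² applied to the unrounded n, rounding
up to an integer at the end (a 1e-12 guard absorbs floating-point ties at
integer boundaries). For the planning scenario 0.75 vs 0.85 at α = 0.05 and
power 0.90 this gives 354 per group (708 in all); the uncorrected value is
cross-validated by a 20,000-replicate Monte-Carlo power simulation of the
pooled z-test rather than by a second closed form.

## The synthetic cohort generator

The generator emulates the *marginal* case mix of a UK rapid-access chest
pain clinic: age truncated-normal on [18, 120] years (default mean 59.4,
SD 11.0, rounded to whole years), sex and risk factors independent
Bernoulli (male 49 %, smoking 41 %, diabetes 8 %, hyperlipidaemia 32 %),
baseline medication classes independent Bernoulli (antiplatelet 22 %,
beta-blocker 5 %, statin 25 %), and pain answers drawn *conditionally on a
sampled typicality category* (19 % typical / 16 % atypical / 65 %
non-anginal): the category is sampled first, then a uniformly random answer
triple consistent with it. Independent per-answer Bernoulli draws could not
hit a target typicality mix exactly, which is why the conditional scheme is
the design. ECG-abnormality prevalence is not reported for the reference
population; the 10 % default is an assumption of this package, exposed as
`p_ecg_abnormal`.

The pathway model (`AdherenceModel`) is four probabilities: an
investigation happens with `p_follow_investigation_recommended` (default
0.59) when recommended — the recommended modality is the one done — and
with `p_investigate_when_not_recommended` (default 0.14) otherwise,
recorded as `other`; each newly recommended medication class is adopted
independently with `p_follow_medication` (default 0.50) and baseline
classes persist; the decision-support tool is flagged as used with
`p_cdss_used` (default 0.86). Cohort concordance is then analytically the
mixture `prev·p_follow + (1 − prev)·(1 − p_not)` with `prev` the
recommendation prevalence, which the test suite verifies by simulation.

What the generator does **not** emulate: risk-factor correlations (marginals
only), site and clinician effects, secular trends, data-entry gaming,
modality substitution and waiting-list effects, or any dependence of
adherence on patient covariates. Passing calibration tests therefore shows
the pipeline's internal consistency, not fidelity to any real clinic; under
the packaged guideline tables the synthetic case mix yields a higher
recommendation prevalence than a real clinic audit would, because marginal
independence puts more mass on older high-risk non-anginal presentations.

Randomness: one global integer seed; each stage (cohort, CDSS-use flags,
pathway) draws from a named `SeedSequence` substream so a stage can be
re-run independently; generate → recommend → simulate → evaluate is
bit-reproducible from (config, seed).

## Numerical and interface choices

* Band membership uses half-open intervals with the top band closed; the
  partition (no gap, no overlap, exact [0, 100] coverage) is validated at
  config load, never at lookup time, as are table totality and both
  monotonicity invariants.
* Cohort CSV files encode booleans as 0/1, categories as lower-case tokens
  and multi-valued fields semicolon-separated with the empty string meaning
  the empty set; absent six-month follow-up is the literal `na` in both
  follow-up columns (in only one of them it is a row error). This keeps
  "followed up, nothing done" and "lost to follow-up" distinguishable in a
  16-column schema.
* Validation errors carry 1-based data-row numbers; a missing mandatory
  column is reported by name before any row is parsed.
* `wald_ci` refuses n = 0 (undefined proportion); the sample-size routine
  refuses p₁ = p₂ (no finite n) and degenerate α or power.
* Problem sizes in the test and acceptance runs — 10,000-patient calibration
  cohorts, 20,000 Monte-Carlo power replicates, 2,001-point band-oracle
  grids — were chosen so every stochastic check sits well inside 3
  Monte-Carlo standard errors of its target while the whole suite runs in
  seconds.

## Known limitations

* The exercise tolerance test (treadmill ECG) is deliberately outside the
  model, as is any contraindication logic for the panel angiography rule.
* The medication rule table is a placeholder; conclusions about medication
  recommendations transfer to a real deployment only after replacing it.
* Wald intervals are known to undercover for small n and extreme
  proportions; they are used here because the audit statistics they
  accompany are descriptive, and interval agreement with historical reports
  at integer precision is limited by the rounding-convention issue above.
* Concordance is a crude feasibility measure: it conflates clinical
  appropriateness with structural barriers (investigation availability,
  prescribing rights), and six-month censoring makes it conservative.
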