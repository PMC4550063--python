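# anginacdss

Decision support and audit statistics for new-onset stable chest pain.

Rapid-access chest pain clinics assess patients with suspected stable angina.
UK guidance (NICE CG95) drives that assessment off a *pre-test probability*
(PTP) of coronary artery disease, looked up from four inputs: sex, age band,
chest-pain typicality and risk-factor status. Pain typicality comes from
three yes/no questions — is the pain constricting, is it brought on by
exertion, is it relieved by rest or GTN — giving *typical* angina (all
three), *atypical* angina (exactly two) or *non-anginal* pain (at most one).
The PTP then selects a first-line investigation (<10 % none, 10–29 % CT
calcium scoring, 30–60 % functional imaging, 61–90 % invasive coronary
angiography; strictly above 90 % an expert-panel rule recommends angiography
directly) and a set of up to three secondary-prevention medication classes
(antiplatelet, statin, beta-blocker).

This package provides, for researchers auditing such a pathway:

* **the rule engine** (`anginacdss.engine`) — pain classification, risk
  stratification, PTP lookup and investigation/medication recommendations,
  driven entirely by an editable YAML guideline config (the packaged default
  carries the CG95 tables);
* **concordance statistics** (`anginacdss.stats`) — whether six-month
  management *followed* the recommendation, with Wald binomial confidence
  intervals p̂ ± z·√(p̂(1−p̂)/n), two-proportion difference intervals, a
  count-based medication-change classification, and the two-proportion
  sample-size formula with the Fleiss continuity correction;
* **a synthetic cohort simulator** (`anginacdss.simulate`) — truncated-normal
  ages, Bernoulli risk factors, pain answers drawn conditionally on a target
  typicality mix, and a Bernoulli adherence model of the care pathway, so the
  whole pipeline runs and is testable without any patient data;
* **a CLI** (`anginacdss recommend | evaluate | simulate | samplesize`).

## Worked example

One patient through the engine:

```python
from anginacdss import PatientPresentation, load_guideline_config, run_cdss

config = load_guideline_config()          # packaged CG95 tables
patient = PatientPresentation(
    patient_id="demo-001", age=58, sex="male",
    smoker=True, diabetes=False, hyperlipidaemia=False, ecg_abnormal=False,
    pain_constricting=True, pain_exertional=True, pain_relieved_by_rest_or_gtn=False,
    group="after",
)
rec = run_cdss(patient, config)
```

prints (two of the three pain features → atypical; smoking → high risk;
the male/55–64/atypical/high-risk PTP cell is 79 %, which lands in the
61–90 % band):

```
typicality      atypical
risk level      high
pre-test prob.  79 %
investigation   invasive_angiography
medications     ['antiplatelet', 'beta_blocker', 'statin']
```

A concordance audit reconstructed from a published-style 2×2 table — 36
patients recommended an investigation of whom 18 had one within six months,
70 recommended none of whom 10 had one anyway:

```python
from anginacdss import concordance_records_from_counts, investigation_concordance

recs, outcomes = concordance_records_from_counts(36, 18, 70, 10)
s = investigation_concordance(recs, outcomes, group="before")
```

```
followed: 78/106 = 74 % (95 CI 65-82 %)
investigated when recommended: 50 % (95 CI 34-66 %)
investigated when not recommended: 14 %
```

From a shell, the planned-study sample size for detecting a rise in
concordance from 75 % to 85 % (two-sided α = 0.05, power 0.90, with
continuity correction):

```
$ anginacdss samplesize --p1 0.75 --p2 0.85
n per group: 354
n total:     708
```

and `anginacdss simulate --seed 7 --out runs/demo` writes a full synthetic
study arm (cohort, recommendations, six-month outcomes, evaluation report,
run metadata) reproducible from the seed.

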