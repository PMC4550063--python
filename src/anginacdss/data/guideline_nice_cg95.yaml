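# Guideline lookup tables for the chest-pain decision-support engine.
#
# ptp_table: pre-test probability (%) of coronary artery disease by sex,
# age band, pain typicality and risk-factor level, transcribed from the
# English national chest-pain guideline (NICE CG95 Table 1, the
# Pryor-modified Diamond-Forrester estimates). "low" = no risk factors,
# "high" = at least one of smoking / diabetes / hyperlipidaemia (and,
# by default, an abnormal resting ECG; see ecg_counts_as_risk_factor).
#
# age_bands: interior cut-points. Four bands: <45, 45-54, 55-64, >=65,
# matching the guideline's age-35/45/55/65 rows. Each ptp_table list has
# one value per band, in band order.
#
# investigation_bands: half-open [lo, hi) intervals partitioning [0, 100]
# (top band closed), each mapping to the guideline's recommended first-line
# investigation: <10% no further investigation, 10-29% CT calcium scoring,
# 30-60% functional imaging, 61-90% invasive coronary angiography.
#
# panel_threshold: above this PTP (%) the expert-panel rule overrides the
# band lookup and recommends invasive angiography.
#
# medication_rules: recommended secondary-prevention drug classes by
# (typicality, investigation-band index). SYNTHETIC STAND-IN: the original
# panel's medication rules were never published; this table is an editable,
# clinically plausible placeholder (escalating from nothing at minimal
# probability to antiplatelet + statin + beta-blocker at high probability).

age_bands: [45, 55, 65]

ptp_table:
  male:
    non_anginal: {low: [3, 9, 23, 49],  high: [35, 47, 59, 69]}
    atypical:    {low: [8, 21, 45, 71], high: [59, 70, 79, 86]}
    typical:     {low: [30, 51, 80, 93], high: [88, 92, 95, 97]}
  female:
    non_anginal: {low: [1, 2, 4, 9],   high: [19, 22, 25, 29]}
    atypical:    {low: [2, 5, 10, 20], high: [39, 43, 47, 51]}
    typical:     {low: [10, 20, 38, 56], high: [78, 79, 82, 84]}

investigation_bands:
  - {lo: 0,  hi: 10,  investigation: none}
  - {lo: 10, hi: 30,  investigation: ct_calcium_scoring}
  - {lo: 30, hi: 61,  investigation: functional_imaging}
  - {lo: 61, hi: 100, investigation: invasive_angiography}

panel_threshold: 90

ecg_counts_as_risk_factor: true

medication_rules:
  non_anginal:
    - []                                  # [0, 10)
    - []                                  # [10, 30)
    - [statin]                            # [30, 61)
    - [antiplatelet, statin]              # [61, 100]
  atypical:
    - []
    - [statin]
    - [antiplatelet, statin]
    - [antiplatelet, statin, beta_blocker]
  typical:
    - [statin]
    - [antiplatelet, statin]
    - [antiplatelet, statin, beta_blocker]
    - [antiplatelet, statin, beta_blocker]
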