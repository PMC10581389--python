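# Default configuration for the QTc-prolongation decision engine.
#
# The points table encodes the Tisdale et al. additive risk score for
# QTc prolongation in hospitalized patients (factor/point constants taken
# from that published score; they are data here, not code, so a site can
# audit or replace them).  The thresholds block carries the algorithm's
# score cutoff for requiring a baseline ECG and the sex-specific QTc
# management limits.
points_table:
  factors:
    - id: age_ge_68
      description: "Age 68 years or older"
      points: 1
    - id: female_sex
      description: "Female sex"
      points: 1
    - id: loop_diuretic
      description: "Receiving a loop diuretic"
      points: 1
    - id: hypokalemia
      description: "Serum potassium <= 3.5 mmol/L"
      points: 2
    - id: baseline_qtc_ge_450
      description: "Baseline (pre-drug) QTc >= 450 ms"
      points: 2
    - id: acute_mi
      description: "Acute myocardial infarction"
      points: 2
    - id: sepsis
      description: "Sepsis"
      points: 3
    - id: heart_failure
      description: "Heart failure"
      points: 3
    - id: one_qt_drug
      description: "One QTc-prolonging drug"
      points: 3
    - id: additional_qt_drugs
      description: "Two or more QTc-prolonging drugs (additional)"
      points: 3
  thresholds:
    ecg_trigger: 7
    high: 11
ecg_thresholds:
  male_ms: 440
  female_ms: 470
  critical_ms: 500
# Triggers that add follow-up monitoring advice on the recommend-with-
# monitoring path (follow-up ECG + physical exam "at specified cases").
monitoring_triggers:
  - prolonged_band
  - dose_escalation
  - second_qt_drug
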