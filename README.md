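# qtcipa — decision support for drug-induced QTc prolongation

Many psychotropic (and other) drugs prolong the heart-rate-corrected QT
interval (QTc), predisposing patients to torsades de pointes and sudden
cardiac death. Mental-health prescribers often have to weigh this risk
without ready access to cardiology. `qtcipa` implements a stepwise
clinical algorithm (eight decision steps, Q1–Q8) that routes a patient
and a proposed drug to one of four terminal recommendations with a
complete audit trail, plus the content-validity statistics used to
validate such instruments with expert rater panels.

**Who it is for:** pharmacists, psychiatrists and clinical-informatics
teams prototyping QTc decision support, and methodologists computing
content-validity indices for survey-validated clinical tools. It is a
research/engineering artifact, not a regulated medical device; clinical
judgment always governs.

## The algorithm

1. **Q1 — drug classification.** The proposed drug is looked up in a
   local, versioned TdP-risk catalog (CredibleMeds-style categories:
   known / possible / conditional risk). An unlisted drug short-circuits
   to *recommend* with a no-QTc-specific-risk rationale.
2. **Q2 — interactions.** Pharmacodynamic stacking (≥ 2 QT-risk drugs)
   and pharmacokinetic interaction (metabolic inhibitor co-prescribed)
   are flagged separately; dose and route cautions are annotated.
3. **Q3–Q6 — additive risk score.** A Tisdale-style points table
   (shipped as auditable config, not code) scores age ≥ 68, female sex,
   loop diuretic, K⁺ ≤ 3.5 mmol/L, baseline QTc ≥ 450 ms, acute MI,
   sepsis, heart failure and QT-drug count. Total < 7 → **recommend**;
   total ≥ 7 without an ECG → **obtain baseline ECG**.
4. **Q7/Q8 — ECG routing.** QT is corrected (Bazett QT/RR^½, Fridericia
   QT/RR^⅓, Framingham, Hodges; default Fridericia) and banded against
   sex-specific limits (440 ms men / 470 ms women / 500 ms critical).
   QTc ≥ 500 ms → **avoid and refer** (immediate cardiology review);
   otherwise → **recommend with monitoring**, with a dose-reduction /
   switch caution when the band is prolonged.

## The validity statistics

For a raters × items matrix of 1–4 Likert ratings (3 or 4 = agreement):

- **I-CVI** = A/N, the fraction of the N raters scoring the item 3 or
  4; items with I-CVI < 0.78 are rejected.
- **Ave-CVI** = mean item I-CVI; ≥ 0.9 reads as excellent validity.
- **PC** = C(N, A)·0.5^N, the binomial probability of that agreement
  arising by chance (exact integer binomials, never float factorials).
- **κ\*** = (I-CVI − PC)/(1 − PC), the chance-corrected index, with the
  usual bands (≤ 0.20 slight … > 0.80 almost perfect).

## Worked example

`patient.json`:

```json
{"patient_id": "demo-001",
 "risk_inputs": {"age_years": 72, "sex": "female",
                 "serum_potassium_mmol_per_L": 3.4, "heart_failure": true},
 "medications": [{"name": "mirtazapine"}],
 "ecg": {"qtc_ms": 482, "correction_formula": "precorrected"}}
```

```sh
qtcipa assess --patient patient.json --drug citalopram
```

prints (trace abridged):

```
Verdict: RECOMMEND_WITH_MONITORING

Rationale
  * citalopram: known risk of TdP.
  * Pharmacodynamic interaction: two or more QT-risk drugs co-prescribed.
  * QTc 482 ms is below the critical cutoff: therapy recommended with follow-up ECG and physical exam.
  * Consider reducing dose or switching to drug of lower effect.

Risk score: 13 points (ELEVATED)
QTc: 482 ms — band PROLONGED, cardiology referral CONSIDER
```

The 13 points are age ≥ 68 (1) + female sex (1) + hypokalemia (2) +
heart failure (3) + one QT drug (3) + additional QT drug (3): the score
demands an ECG, the ECG shows a prolonged-but-subcritical QTc, so
therapy proceeds with monitoring and a dose-reduction caution.

For a rater panel:

```sh
qtcipa simulate ratings --raters 30 --items 8 --p-agree 0.93 --seed 7 --out ratings.csv
qtcipa validate-survey ratings.csv
```

```
item           N   A   I-CVI  kappa*  band            verdict
Q1            30  28    0.93    0.93  almost perfect  RETAIN
...
Q5            30  27     0.9     0.9  almost perfect  RETAIN
Q6            30  29    0.97    0.97  almost perfect  RETAIN
Ave-CVI = 0.93 (excellent content validity)
```

Note κ* equals I-CVI at two decimals: with 30 raters the chance-
agreement probability is ~4×10⁻⁷, so the correction is negligible.

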