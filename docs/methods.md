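# Methods

## The decision procedure

The engine is a deterministic rule system: eight ordered steps, each of
which either terminates with a verdict or passes control to the next.
Terminal verdicts, from least to most restrictive: RECOMMEND,
RECOMMEND_WITH_MONITORING, OBTAIN_BASELINE_ECG, AVOID_AND_REFER.
Determinism and totality are design requirements — every syntactically
valid patient reaches exactly one verdict, and clinical edge values
(boundary scores, boundary QTc) never raise. Each run returns the full
ordered trace (step id, input summary, outcome) so the verdict is
auditable after the fact.

Assumptions worth making explicit:

- **The catalog is the authority on drug risk.** The engine does not
  reason about pharmacology; it trusts the loaded drug → category
  table. A drug in no category terminates at Q1 with RECOMMEND — the
  minimal reading of a classification-gated first step — and the
  rationale says so prominently rather than implying the drug was
  assessed as safe.
- **Conditional-risk drugs** count toward the QT-drug stack only when
  the patient record asserts the triggering condition
  (`conditional_triggers_present`); otherwise they add a caution note
  only. This mirrors the public classification's semantics without
  inventing point values.
- **Interaction findings do not alter the verdict.** Dose, route,
  pharmacodynamic stacking and pharmacokinetic-inhibitor flags annotate
  the rationale; no rule attaches points or routing to them, because
  the underlying procedure defines none. The two interaction flags are
  kept separate and explicitly defined (stack count ≥ 2 vs inhibitor
  co-prescription) precisely because conflating them is a known
  ambiguity in tools of this kind.

## The risk score

The score is additive over independent factor predicates; the point
constants ship as data (`data/default_config.yaml`) encoding the
published Tisdale factors: age ≥ 68 y (1), female sex (1), loop
diuretic (1), serum K⁺ ≤ 3.5 mmol/L (2), baseline QTc ≥ 450 ms (2),
acute MI (2), sepsis (3), heart failure (3), one QT-risk drug (3), two
or more QT-risk drugs (+3). Any table with the same schema can be
loaded; factor ids map to a code-side predicate registry, so constants
are auditable and replaceable without touching logic. That score was
validated in admitted (cardiac-care) patients; outpatient use is an
extrapolation the report text flags rather than hides.

Two numerical decisions:

- **Missing labs score 0 but are reported "not assessed".** A decision
  aid must distinguish "normal" from "unknown"; silently treating an
  absent potassium as normal would understate risk invisibly. The
  baseline-QTc factor likewise reads only an explicitly recorded
  pre-drug QTc (`baseline_qtc_ms`), not the ECG supplied for Q6–Q8
  routing, because the score is defined on pre-treatment inputs.
- **A total of exactly 7 routes to the baseline-ECG path.** The step
  wording claims 7 for both branches ("≤ 7" recommend, "≥ 7" ECG); the
  tie resolves to more monitoring, consistent with the cited score's
  moderate-risk band starting at 7.

## QT correction and banding

Four standard corrections are implemented (Bazett QT/RR^½, Fridericia
QT/RR^⅓, Framingham QT + 154(1−RR), Hodges QT + 1.75(HR−60)), plus a
pass-through for pre-corrected values; all agree at RR = 1 s, which the
tests use as a fixed point. No formula is mandated by the underlying
procedure, so the choice is an explicit, traced parameter; the default
is Fridericia (smaller rate-dependent bias than Bazett at tachy- and
bradycardic rates).

Banding uses sex-specific normal upper limits (440 ms men, 470 ms
women) and a 500 ms critical cutoff, all configurable. Boundary policy
is conservative throughout: a QTc exactly at the sex limit is
PROLONGED, and exactly 500 ms is CRITICAL (avoid-and-refer). The
"abnormal T-wave morphology" caveat on the no-action row is carried as
free text only — no waveform processing is attempted.

## Validity statistics

For each item, N is its own non-missing rating count and A the count of
ratings in {3, 4}; I-CVI = A/N is kept as an exact ratio until
reporting. PC is the binomial(N, ½) mass at A, computed with exact
integer binomial coefficients over 2^N (arbitrary-precision rationals,
converted to float once): floating factorials lose precision long
before they overflow near N = 171. κ* = (I-CVI − PC)/(1 − PC).

Per-item N (rather than a panel-wide N) is the only reading under which
reported index ranges can fall below the coarsest grid a full panel
allows, and it is what a rater skipping an item actually implies.

The published interpretation bands for κ* touch at their endpoints
(0–0.20, 0.21–0.40, …); for a continuous statistic the gaps must close,
so the implementation uses half-open intervals: < 0 no agreement,
[0, 0.20] slight, (0.20, 0.40] fair, (0.40, 0.60] moderate,
(0.60, 0.80] substantial, (0.80, 1] almost perfect. Item rejection is
strict: I-CVI < 0.78 rejects, 0.78 exactly retains. At N = 30 the
smallest retained agreement count is therefore A = 24 (0.80), and A=23
(0.767) rejects — verified by enumeration.

Statistics are computed at full precision and reported at two decimals,
rounding half away from zero, matching the conventional 2-dp
presentation of CVI tables. A useful regime fact the tests pin down:
for N ≥ 20 and A/N ≥ 0.78, |κ* − I-CVI| < 0.01 — the chance correction
is negligible for well-rated items on panels of that size, which is why
reported I-CVI and κ* ranges typically coincide.

## Synthetic data

`simulate_ratings` draws each present cell independently: agreement
(uniform over {3, 4}) with probability `p_agree`, disagreement (uniform
over {1, 2}) otherwise; cells go missing independently with probability
`p_missing`, and an all-missing item is re-drawn (bounded retries) so
the matrix invariant holds. This is the minimal generative model under
which I-CVI is unbiased for `p_agree`, giving the recovery tests a
closed-form target. Defaults (30 raters × 8 items) mirror a typical
expert-panel validation. What it deliberately does not model: rater
effects (systematically harsh or lenient raters), item difficulty
correlations, or ordinal structure beyond the agree/disagree dichotomy
— so passing recovery tests show estimator correctness under
independence, not robustness to correlated rater behavior.

`generate_patients` draws independent Bernoulli risk factors at
configurable prevalences (defaults sketch a mixed adult mental-health
population: loop diuretic 0.10, acute MI 0.02, sepsis 0.02, heart
failure 0.05, hypokalemia 0.10, inhibitor co-prescription 0.10),
Poisson medication counts (mean 1.5) sampled from the loaded catalog,
age ~ N(45, 16²) clipped to 18–95, and per-sex QTc from a truncated
normal on (300, 700) ms (means 415/425 ms, SD 22 ms; ECG available with
probability 0.5). These are plausibility choices for exercising every
code path, not a calibrated pharmacoepidemiological model:
co-prescription patterns, dose information and lab–drug correlations
are absent, so cohort-level verdict frequencies from the simulator
characterize the engine, not any real population.

## Problem sizes and determinism

All routing checks are exhaustive rather than sampled: the terminal
verdict grid (4 drug categories × scores 0–15 × 6 ECG states × 2 sexes
= 768 cases) and the 2^8 × 3 score-factor enumeration run against
independently coded truth tables in well under a second. Stochastic
checks are seeded (numpy `default_rng`; hypothesis derandomized): the
estimator-recovery check uses 10,000 replicates of 30 × 8 panels per
agreement level, where the Monte-Carlo standard error of the mean I-CVI
is ~3 × 10⁻⁴, making the 3-SE acceptance band a sharp test of
unbiasedness.

## Known limitations

- The engine encodes one published procedure; it does not adjudicate
  between competing QTc risk scores or thresholds, and deliberately
  makes no drug-substitution suggestions.
- The bundled drug catalog is an illustrative fixture (~20 drugs), not
  a clinical reference; real deployments must load a maintained list.
- Expanded risk factors (hypomagnesemia, bradycardia, ischemia,
  structural heart disease) can be added by registering a predicate in
  `scoring.FACTOR_PREDICATES` and adding the matching row to a custom
  points table; none are defined by default, and a table row without a
  registered predicate is rejected at load rather than silently scoring
  zero.
- No probabilistic output: the QTc–arrhythmia dose-response is
  contested, so the engine emits categorical bands and verdicts only.
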