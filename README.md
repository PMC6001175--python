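# hbresponse

Predicting breast-cancer pathologic response to neoadjuvant chemotherapy
(NAC) from tumor subtype and near-infrared hemoglobin biomarkers.

## The problem

Pathologic complete response (pCR) to NAC varies strongly with breast-cancer
subtype (HER2+, ER+/HER2−, triple-negative), and identifying likely
responders early — ideally before treatment, or within the first one or two
chemotherapy cycles — would allow treatment to be personalized. Tumor
vascularity, measured as the maximum total hemoglobin concentration (tHb,
μmol/L) from ultrasound-guided near-infrared diffuse optical imaging, is a
noninvasive biomarker of angiogenesis: responders start with higher tHb and
show a sharp vascular collapse after the first cycle, quantified as the
percentage of the baseline value remaining (%tHb).

`hbresponse` is a reusable implementation of that prediction framework for
biostatisticians working with longitudinal biomarker cohorts:

- **cohort model** — patient records (subtype flags, Nottingham score NS,
  mitotic count MC, Miller-Payne grade) and per-visit hemoglobin maxima,
  with CSV readers/writers and the embedded 22-patient study table;
- **hemoglobin biomarkers** — Beer–Lambert unmixing of four-wavelength
  (740/780/808/830 nm) absorption maps into oxy/deoxy-hemoglobin with
  nonnegative least squares, ROI maxima, replicate averaging with motion
  exclusion, and the %tHb / %US normalizations;
- **screening** — Spearman correlation screen against the Miller-Payne grade
  with a collinearity rule, Welch two-sample t-tests (raw or
  summary-statistic form), and a dummy-variable poolability test for
  combining cohorts;
- **prediction** — logistic regression fitted by a hand-written
  iteratively-reweighted-least-squares maximum-likelihood routine, exposed
  as a scikit-learn-compatible estimator (`LogisticResponseModel`) with
  separation diagnostics and optional ridge/Firth stabilization;
- **evaluation** — native ROC/AUC (threshold sweep ≡ Mann–Whitney),
  exhaustive enumeration of the C(11, 6) = 462 train/test transfer splits,
  mean-AUC confidence intervals, confusion metrics at the 0.5 rule, and a
  runner for the four published predictor-group families;
- **synthetic cohorts** — a seeded generator reproducing the study's group
  distributions (responders 84.8 ± 11.3 μmol/L baseline tHb and 72 ± 22%
  cycle-1 %tHb vs 67.9 ± 16.2 μmol/L and 102 ± 12% for non-responders,
  non-separating day-7 values), so the full pipeline is testable without
  patient data.

## The model

Response is the Miller-Payne dichotomy Y = 1 for grades 4–5 (pCR or near
pCR) and 0 for grades 1–3. Given predictors x₁…x_k — subtype codings
(HER2, ER coded 0 when positive, TN), NS, baseline tHb, and %tHb at cycles
1–3 — the response probability is logistic,

    pr(Y = 1 | x) = 1 / (1 + exp(−(β₀ + Σₙ βₙ xₙ))),

with β estimated by maximum likelihood. A patient is classified as a
responder when the fitted probability strictly exceeds 0.5. Models are
evaluated by fitting on each enumerated 38-patient training set (a fixed
32-patient earlier cohort plus 6 of the 11 transferable HER2+ patients) and
scoring the complementary 16-patient test set; the mean of the 462 test
AUCs, with a binomial 95% CI, summarizes each predictor set.

## Worked example

```python
from hbresponse import (
    load_fixture_table1, welch_t_from_summary, percent_tHb,
    generate_cohort, new_cohort_config, early_cohort_config,
    design_frame, concat_cohorts, evaluate_model_over_splits, study_split_scheme,
)

cohort = load_fixture_table1()
print("patients:", len(cohort),
      "| HER2+:", sum(p.her2 for p in cohort.patients),
      "| responders (MP 4-5):", sum(p.responder for p in cohort.patients))

t = welch_t_from_summary(84.8, 11.3, 13, 67.9, 16.2, 9)
print(f"baseline tHb difference: {t.mean_diff:.1f} umol/L (P = {t.p_value:.3f})")

print(f"cycle-1 %tHb for the worked responder example: "
      f"{percent_tHb(85.8, 36.3, ndigits=0):.0f}%")

early = generate_cohort(early_cohort_config(seed=0))
new = generate_cohort(new_cohort_config(seed=1))
scheme = study_split_scheme(new, early)
frame = design_frame(concat_cohorts(early, new))
for group in (["tHb"], ["tHb", "pct_tHb_cyc1"]):
    _, test, cm = evaluate_model_over_splits(scheme, frame, group)
    print(f"{' + '.join(group):24s} mean test AUC {test.mean_auc:.2f} "
          f"(95% CI {test.ci_low:.2f}-{test.ci_high:.2f}) over {test.n_splits} splits")
```

prints

```
patients: 22 | HER2+: 11 | responders (MP 4-5): 13
baseline tHb difference: 16.9 umol/L (P = 0.018)
cycle-1 %tHb for the worked responder example: 42%
tHb                      mean test AUC 0.61 (95% CI 0.57-0.66) over 462 splits
tHb + pct_tHb_cyc1       mean test AUC 0.90 (95% CI 0.88-0.93) over 462 splits
```

The first three lines are fixed by the embedded cohort table and the
published group summaries: 13 of 22 patients are responders, the responder
groups differ in pretreatment tHb by 16.9 μmol/L (Welch P = 0.018), and the
worked responder example retains 42% of baseline hemoglobin after one
cycle. The AUC lines are computed on one synthetic cohort draw and vary
with the seed; adding cycle-1 %tHb to baseline tHb raises the mean test AUC
substantially, which is the qualitative conclusion the evaluation scheme is
designed to expose.

A command-line interface wraps the same pipeline:

```
hbresponse simulate --preset new --seed 1 --out-dir cohort/
hbresponse screen --patients cohort/patients.csv --measurements cohort/measurements.csv
hbresponse run --seed 1 --out-dir results/
```

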