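# Methods

## Outcome and predictors

The outcome is the Miller-Payne dichotomy: grade 4–5 (over 90% loss of
tumor cellularity, or no residual invasive tumor) versus grade 1–3. The
dichotomy is fixed; `responder` is always derived from the grade and cannot
be set independently.

Predictors are used on their natural scales: subtype indicators coded so
that 1 marks the level with higher pCR probability (TN = 1 for
triple-negative, HER2 = 1 for HER2-positive, ER_code = 1 for ER-negative),
the Nottingham score (3–9), baseline maximum tHb in μmol/L, and %tHb
(percent of the pretreatment maximum) at the end of cycles 1–3. ER cases
reported as weakly positive are coded ER-positive. Patients presenting with
two adjacent masses are modelled as a single record.

## Hemoglobin biomarkers

Absorption maps μa(λ) at 740, 780, 808 and 830 nm are unmixed per voxel by
solving the overdetermined Beer–Lambert system
μa(λ) = ln(10)·10⁻⁶·[ε_oxy(λ)·C_oxy + ε_deoxy(λ)·C_deoxy] for nonnegative
concentrations in μmol/L. The unconstrained least-squares solution is used
wherever it is already nonnegative; offending voxels are re-solved with
NNLS. The embedded extinction coefficients come from the OMLC (Prahl)
compilation and are configuration, not ground truth: any table with a
full-rank 4×2 design may be substituted, and the decadic-vs-natural-log
convention is a single documented constant, so the forward/inverse pair is
self-consistent either way. Tomographic image reconstruction itself is out
of scope; maps are taken as given or simulated.

Each visit is summarized by the maxima of tHb, oxyHb and deoxyHb over the
ultrasound-derived ROI (the three maxima may occur at different voxels),
then averaged over the 5–10 quality replicate acquisitions after excluding
motion-flagged ones; a visit with every replicate flagged is an error, not
a silent zero. %tHb and %US are plain percentage ratios against the
pretreatment value and require a positive baseline; %tHb is reported at
full precision internally and rounded to integer percent only for display.

## Logistic fitting

The Bernoulli log-likelihood is maximized by Newton–Raphson (IRLS) with
step halving, from a zero start. Convergence is declared when the
log-likelihood improves by less than 1e−8 (cap 100 iterations); these
values make small-cohort fits bit-stable at reporting precision. The
covariance is the inverse observed information at the optimum; Wald tests
are two-sided normal.

Separation needs explicit handling because the likelihood also flattens
near a divergent "MLE at infinity", so a small log-likelihood increment
alone does not certify an interior maximum. A fit whose coefficients exceed
15 on the standardized scale (slopes multiplied by the predictor SD, the
intercept read at the predictor means) is flagged as separated and never
reported as converged; the bound is a heuristic chosen far outside any
plausible per-SD log-odds ratio in this domain. Plain maximum likelihood is
the default, matching the published analysis; ridge (α = 1e−4 on
standardized predictors) and Firth (Jeffreys-prior score adjustment)
stabilizations are available behind a flag and always labelled in the
output. Estimates are invariant (in fitted probabilities) to affine
predictor rescaling; standardization is used only for the divergence bound
and the ridge metric.

## Screening statistics

Spearman's rho uses midranks for ties with the t-approximation p-value
(t = rho·√((n−2)/(1−rho²)) on n−2 df), delegated to `scipy.stats.spearmanr`
which implements exactly this definition; an exact permutation variant
(n ≤ 10) exists as a small-sample oracle. Group comparisons default to the
Welch unequal-variance t-test with Welch–Satterthwaite df — from the
printed group summaries (84.8 ± 11.3, n = 13 vs 67.9 ± 16.2, n = 9) it
reproduces the published P = 0.018 where the pooled form gives a smaller p;
a pooled option exists behind a flag. The predictor screen drops one member
of any pair with |rho| above 0.8 (the threshold at which the mitotic count
was dropped for its rho = 0.82 with the Nottingham score), keeping subtype
flags unconditionally (TN is retained for clinical use despite weak
marginal correlation) and preferring NS over MC within that pair for
clinical interpretability; otherwise the member less correlated with the
grade is dropped. No multiple-testing correction is applied, matching the
published analysis.

Before two cohorts are pooled for training, a dataset indicator (0 = old,
1 = new) is appended to the stacked design and the combined model refitted;
the two-sided Wald p for the indicator coefficient is the poolability
evidence. Its type-I error is verified by simulation to sit within 3
binomial SE of 5% under a shared population.

## Evaluation scheme

Because the earlier training cohort lacked dual-HER2-blockade patients, six
of the eleven HER2+ patients of the new cohort are moved into training.
All C(11, 6) = 462 subsets are enumerated exhaustively in lexicographic
order — the published account describes random selections but notes they
cover all 462 combinations, and determinism is preferable. Each split
trains on 38 patients (32 fixed + 6 transferred) and tests on the remaining
16; per-split fits that do not converge (separated training data, which
does occur at these sizes with strong predictors) are excluded from the
mean with a reported count rather than silently included, and a predictor
set whose every split separates is reported with NaN AUCs and a full
exclusion count so the four-group report always has its complete 40-row
structure.

ROC curves sweep thresholds over the distinct scores (ties grouped); the
trapezoidal area equals the Mann–Whitney AUC exactly and the identity is
enforced as a property test rather than assumed. The sentence-level
ambiguity about a "threshold of 0.5" in ROC construction is resolved as:
the ROC sweeps all thresholds, and 0.5 is used only to classify responders
(probability strictly greater) for the confusion metrics, which are pooled
over all test predictions across splits (a single percentage per model,
matching the published reporting style; per-split averaging is not
offered). An undefined metric (zero denominator) is NaN, never 0.

The 95% CI for the mean AUC defaults to the normal-approximation binomial
interval m ± 1.96·√(m(1−m)/N) with N the number of splits, clipped to
[0, 1]; an empirical 2.5/97.5-percentile interval is available. The exact
published "binomial formula" is not recoverable from the text, so the two
implemented readings bracket it and neither is asserted to match the
published CIs numerically.

## Synthetic cohorts

The generator emulates the study conditions: 22 patients split 11/6/5
across HER2+ / ER+/HER2− / TN with per-subtype responder rates 0.91 / 0.17
/ 0.40; baseline maximum tHb N(84.8, 11.3²) μmol/L for responders and
N(67.9, 16.2²) for non-responders, truncated at 0 (normality is the
minimal assumption consistent with the published means/SDs and the t-tests
applied to them); cycle-1 %tHb N(72, 22²) vs N(102, 12²). Cycle-2/3 group
means are not published individually, only mean differences of 26% and
25%, so the non-responder trajectory defaults to flat at 100% with the
responder mean derived from the difference and SDs carried over from cycle
1. Day-7 parameters are likewise unpublished; both groups default to
N(95, 15²) so the day-7 comparison is non-separating at the study size, as
observed. %US trajectories use the published per-cycle group summaries.
Within a responder group the Miller-Payne grade is uniform on {4,5} or
{1,2,3} (no within-group distribution is published); the Nottingham score
is shifted upward for responders with configurable strength, and the
mitotic count is generated log-normally from NS so the pair reproduces a
strong (rho ≈ 0.8+) correlation. Baseline tHb is conditioned on responder
status only — per-subtype baseline distributions are not published.

Each visit's stored maximum is the mean of 5–10 simulated replicates with
5% coefficient-of-variation noise (the reported longitudinal repeatability
is 5–10%) after removing motion-flagged replicates (10% corruption
probability; at least one replicate always survives). Every patient draws
from an independent substream of the root seed, so enlarging a cohort
never perturbs earlier patients; when an exact subtype composition is
requested, the label sequence is shuffled from its own substream.

The earlier (2008–2011) training cohort is emulated with 32 patients split
5/21/6 (the single ER−/PR+/HER2− patient is folded into the ER+/HER2−
bucket), no day-7 visit, and a HER2+ responder rate of 0.45 reflecting
single-agent-trastuzumab-era pCR; all distributional parameters otherwise
match the new cohort so the two are poolable by construction.

What the generator does not emulate: within-patient correlation of %tHb
across cycles (draws are independent given responder status), subtype-
specific hemoglobin trajectories, tumor geometry, dropout, or measurement
error structure beyond i.i.d. replicate noise. Passing tests therefore
demonstrate that the pipeline recovers the structure the generator encodes
— not that the published AUC values themselves are reproduced, which would
require the unpublished per-patient data.

## Problem sizes in the test suite

Law-of-large-numbers checks on the generator use 10⁵ baseline-only
patients; calibration checks use 200 seeds at n = 5000 (parameter
recovery) and 500 seeds at n = 200 (poolability type-I error). The
predictor-ordering check draws cohorts at twice the study size (64
training, 44 test-pool patients; same subtype mix, group distributions and
462-split scheme) so that the per-seed mean test AUC is stable enough for
a deterministic ordering assertion; at the study size itself the 16-patient
test sets make single-seed mean AUCs too noisy for a ≥95%-of-seeds
criterion, though the ordering still holds in the large majority of draws.

## Known limitations

- The published per-patient hemoglobin values are not available, so all
  end-to-end numbers are synthetic-cohort quantities; only the embedded
  cohort table, the printed group summaries and the worked %tHb example
  are fixed points.
- Wald inference after separation is unreliable and is flagged, not
  suppressed.
- The poolability test assumes the two cohorts share predictor columns and
  a common logistic form; it tests only a location shift of the linear
  predictor via the intercept indicator.
- The mean-AUC "binomial" CI treats the 462 enumerated AUCs as if
  independent, which they are not (they share the 32 fixed training
  patients); the published caveat to the same effect applies here too.
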