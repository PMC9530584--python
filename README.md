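# dffglu

Detrended fluctuation analysis of continuous glucose monitoring (CGM) traces
as a beta-cell-function surrogate for telling **latent autoimmune diabetes in
adults (LADA)** apart from **type 2 diabetes (T2DM)**.

LADA patients lose insulin secretion much faster than T2DM patients, and the
resulting erratic glucose dynamics are visible in a week of CGM wear. This
package implements the full analysis chain for exploiting that signal:

1. **Detrended fluctuation function.** For a glucose series *x(t)* the
   mean-centred cumulative sum *y(t) = Σᵢ≤ₜ (x(i) − x̄)* is partitioned into
   ⌊N/l⌋ consecutive windows of length *l*, each window is detrended by an
   ordinary-least-squares line, and

   *F_d(l) = √( (1/(m·l)) Σ (y − ŷ)² )*

   is the pooled RMS residual. *F_d(l)* is used directly as a per-patient
   score (not reduced to a DFA scaling exponent). At 5-minute sampling,
   *l* = 100 windows span 8 h 15 min; one day holds 288 samples.
2. **Scale selection.** *F_d(l)* is computed for every integer *l* in
   [2, 130] and the working scale *l\** maximizes the absolute Spearman
   correlation |r| between *F_d(l)* across patients and fasting C-peptide
   (FCP), the standard proxy of residual beta-cell function.
3. **Classification.** *F_d(l\*)* and the classical CGM metrics — time in
   range (TIR, 3.9–10.0 mmol/L), mean glucose, SD, MAGE, %CV — are compared
   as LADA-vs-T2DM classifiers via ROC analysis (AUC with DeLong 95% CI,
   Youden-optimal cutoff, sensitivity/specificity), Cohen's kappa against
   the clinical diagnosis, and stratified 10-fold cross-validation in which
   both *l\** and the cutoff are re-tuned on every training set.
4. **Synthetic cohorts.** Because matched CGM + C-peptide cohorts are rarely
   shareable, a calibrated generator produces two-class cohorts with a
   planted monotone inverse coupling between C-peptide and glycemic
   variability, so the whole chain can be exercised and validated end to end.

The estimators follow scikit-learn conventions (`fit`/`transform`/`predict`,
`get_params`, trailing-underscore fitted attributes) and compose with
sklearn pipelines: `FluctuationProfiler` (traces → *F_d(l)* feature matrix),
`GlycemicMetricsExtractor`, `ScaleSelector`, `YoudenThresholdClassifier` and
`DffScaleClassifier` (scale selection + thresholding in one classifier).

## Worked example

Simulate the default study-sized cohort (60 LADA-like, 120 T2DM-like, 7 days
of 5-minute samples) and run the full analysis:

```bash
$ dffglu run --seed 1 --out demo/
l* = 97 (r_fcp = -0.858)
F_d(97) AUC = 0.769 [0.686, 0.852], cutoff = 25.451, sens = 66.7%, spec = 86.7%
kappa = 0.542
CV mean test AUC = 0.768
```

Reading the output: the window length whose fluctuation value is most
rank-correlated with fasting C-peptide is *l\** = 97 samples (≈8 h), with
Spearman r = −0.858 — patients with more residual insulin secretion have
flatter multi-hour glucose excursions. Used as a classifier, *F_d(97)*
separates the two classes with AUC 0.769 (the best of the six markers on
this cohort); thresholding it at the Youden cutoff recovers the diagnosis
with 66.7% sensitivity, 86.7% specificity and chance-corrected agreement
κ = 0.542; the held-out AUC over 10 stratified folds (0.768) matches the
training AUC, so the two tuned parameters do not overfit.

`demo/` then contains `report.json` (everything above plus per-fold rows),
`correlation_curve.csv` (r vs *l* for FCP and 2-hour C-peptide),
`cohort_summary.csv` (class medians/IQRs with Shapiro-gated t /
Mann-Whitney p-values), `markers.csv` and `report_folds.csv`.

The same stages are available piecewise — `dffglu simulate`, `metrics`,
`dff`, `select-scale`, `classify` — for running on real exported CGM CSVs
(`patient_id,timestamp,glucose_mmol_l`; mg/dL input via `--units mgdl`), and
from Python:

```python
from dffglu import CohortConfig, synthesize_cohort, profile_matrix, DffScaleClassifier

cohort = synthesize_cohort(CohortConfig(seed=1))
F = profile_matrix(cohort.traces, 2, 130)           # (180, 129) F_d matrix
clf = DffScaleClassifier().fit(F, cohort.labels, fcp=cohort.fcp)
print(clf.l_star_, clf.cutoff_, clf.predict(F[:3]))
```

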