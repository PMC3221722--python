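# Methods

`mirnaprog` implements an analytical-validation and prognostication
workflow for probe-level miRNA microarray data from FFPE tumour specimens,
together with a synthetic-cohort generator that reproduces the statistical
structure such studies rely on. This note records the models, the defaults
and why they were chosen, and what the synthetic results do and do not say
about real data.

## Signal model of the generator

Probe-level intensities are lognormal on the log2 scale. For measurement
probe `p` of probe set `g` on an array of sample `s`:

    log2 I(p, s) = mu_g + b_{g,s} + delta * 1[g in signature, y_s = 1]
                   + s_p * u + eps_{p,s}

* `mu_g` — cohort-level baseline per probe set, drawn once: with
  probability `frac_expressed` (0.92) from N(`expressed_log2_mean` = 8.0,
  `expressed_log2_sd` = 0.8), otherwise from the background distribution
  N(6.45, 0.25). Baselines are shared across samples — samples are highly
  correlated, as real arrays of the same tissue type are.
* `b_{g,s}` — per-sample biological deviation, N(0, `bio_log2_sd` = 1.0).
  This is the scale that makes the classification task non-trivial: the
  planted class shift `delta` (default 1.5 log2 units on 12 human probe
  sets) is 1.5 biological standard deviations per feature, which keeps
  leave-one-out accuracies in the 0.9 range rather than saturating at 1.0
  and exercises the data-driven choice of signature size.
* `u = log2(input_ng / 600)` and `s_p ~ N(0, input_sensitivity_sd = 0.15)`
  — a fixed per-probe sensitivity to RNA input deviation. This probe×input
  interaction is what makes the self-self correlation of two replicates
  decay with the input *ratio* between them: with independent noise alone,
  the correlation of an 80 ng / 640 ng pair would exceed that of an
  80 ng / 160 ng pair (the 640 ng replicate is less noisy), the opposite of
  the observed ordering.
* `eps` — replicate noise with sd `sqrt(noise_log2_sd_base^2 +
  noise_input_coeff^2 / input_ng)`; low-input hybridizations are noisier.

Background probes are drawn from N(6.45, sd `sqrt(0.25^2 + 0.25^2)`) per
array and are unaffected by RNA input, matching the observation that
background level is unrelated to input amount.

### Analytical conditions

* **RNA input** scales measurement-probe intensities by the linear factor
  `1 + input_response_slope * (input_ng − 600)` (slope 0.0002/ng; at 80 ng
  the factor is 0.9). The scale response is deliberately mild — in the
  reference data the mean-signal slope is small while detection counts
  respond more strongly, and prognosticator calls are robust across the
  80–640 ng range — so most of the input effect enters through noise and
  the per-probe sensitivity.
* **ATP-mix dilution** and **chip lot** add replicate noise only. These are
  null conditions by construction (the study conditions the generator
  emulates found no effect); users who want to inject an effect for
  sensitivity analyses can perturb the rendered matrices directly.
* **Extraction kit.** The HP kit maps `I -> bg + 0.72 * o_g * (I − bg)`
  with `bg = 2^6.45`: above-background signal is reduced to 72% (the ratio
  of above-background mean intensities between the two kits) with
  per-probe-set lognormal offsets `o_g` (sd `extraction_probe_sd` = 0.3
  log2, mean-normalized to 1).
* **Labeling kit.** The old kit applies the same affine form with
  compression `labeling_f_compression` = 0.24 (the ratio of
  above-background means between old- and new-kit hybridizations) and
  stronger offsets (`labeling_probe_sd` = 2.0 log2).

Kit offsets are drawn **per probe set** and broadcast to probes, not per
probe: extraction and labeling chemistry act on the RNA species, and
probe-level offsets would largely be absorbed into the probe-effect term of
median-polish summarization, which would make kit batches invisible to
PCA. The sd of 2.0 log2 (4-fold) for labeling offsets is consistent with
published comparisons of miRNA kits reporting 5–20-fold per-species signal
differences, and is what makes a sample re-processed with the other
labeling kit land farther from itself in score space than two different
samples processed alike. The extraction offset (0.3 log2) is kept small
because prognosticator calls are robust to the extraction kit in the
emulated study.

All randomness flows from a single integer seed through named
`SeedSequence` spawn keys (structure / kit / sample / array / replicate
streams), so cohorts, sub-streams and later-rendered condition replicates
are individually bit-reproducible.

### Survival

Recurrence labels are Bernoulli(0.5). Recurrence cases receive exponential
event times with hazard 1/24 events/month (median ≈ 17 months, a plausible
time-to-relapse scale for resected stage I disease); recurrence-free cases
are censored uniformly in [32, 68] months, honouring the minimum 32-month
follow-up of the emulated cohort. No competing risks, no covariate effects
on hazard.

### Calibration

Defaults were calibrated analytically from the lognormal model and
confirmed with `qc_report` so that a 20-array default cohort reports mean
signal ≈ 374 (reference magnitude 349), mean background ≈ 90 (89.3) and
≈ 2030 detected probe sets of 2,500 (reference 2,432 at a comparable
fraction of the array). Desk-scale dimensions — 2,000 human + 500 other
probe sets, 4 probes each, 200 background probes — keep the full test
suite in minutes; all dimensions are configurable.

## QC metrics

* Detection dialect: a probe is detected when its one-sided empirical p
  against the array's background probes, `(1 + #{bg >= x}) / (1 + #bg)`,
  is ≤ alpha; a probe set when the one-sided Wilcoxon rank-sum of its
  probes against the background probes gives p ≤ alpha. Default alpha
  0.06. `≤` rather than `<` so that alpha = 1 detects everything. The
  rank-sum uses exact enumeration for small tie-free samples and the
  tie-corrected normal approximation otherwise.
* Self-self correlations are Pearson on log2 intensities of all
  measurement probes, without background subtraction (subtracting
  background did not change conclusions in the emulated study).
* The input-deviation regression uses `|log2(input_A/input_B)|` as the
  pair covariate by default (halving and doubling are equivalent
  perturbations); `abs-ng` is available. For categorical conditions (lot)
  the deviation is a same/different indicator.
* Group comparisons default to equal-variance t / fixed-effects ANOVA
  (the convention of the emulated analyses); Welch is available.

## Summarization

* `avg_diff_raw` — the classifier's input: per probe set, the arithmetic
  mean of its perfect-match probe intensities on the linear scale, no
  background correction, no cross-array normalization. (The platform has
  no mismatch probes, so "average difference" reduces to this mean.)
* `rma_like` — the PCA/correlation input: log2, quantile normalization
  across arrays (ties get the mean of the reference quantiles they span),
  then per-probe-set median polish (tolerance 1e-6, max 20 sweeps); the
  expression index is overall + array effect. The RMA convolution
  background model is omitted — the pipeline is background-free
  throughout; a shift-subtract option was considered and rejected as it
  would make the two modes inconsistent.

## PCA and between-kit variance

Features are centered (not scaled) across samples and decomposed by SVD;
the largest-|loading| entry of each component is made positive so runs are
reproducible. Between-group variance on a component is eta² =
SS_between/SS_total of that component's scores. The paired-kit report
computes, in the first-two-component score space, the mean
within-sample/between-kit distance over paired samples and the mean
between-sample/within-kit distance; their ratio > 1 operationalizes "a
sample is farther from itself across kits than from other samples within a
kit". No batch correction is provided: the remedy for a dominant kit
effect is holding the kit constant, not adjusting it away.

## Prognosticator

Features (human probe sets, `avg_diff_raw` by default) are ranked by the
pooled-variance two-sample t statistic between outcome classes, ordered by
decreasing |t| with ties broken by feature id. A linear-kernel SVM
(C = 1, configurable) is trained on top-ranked features after z-scoring
each feature with the training mean/sd. Zero pooled variance resolves to
|t| = +inf when the class means differ and 0 otherwise; inside tiny inner
folds a single-member class is tolerated (its sum of squares is zero), and
only an empty class is degenerate. A decision value exactly on the
boundary is called 0 ("no recurrence").

Two evaluation schemes:

* **Monte-Carlo**: R random 2/3–1/3 splits (unstratified by default;
  splits that lose a class in training are redrawn and counted). Within
  each training set a leave-one-out loop records the top-k ranking of each
  fold; the k most frequent features (ties: higher mean |t|, then id) are
  the consensus signature, the SVM is trained on them, and accuracy is
  measured on the held-out third. The 95% CI is mean ± 1.96·sd/√R over
  replicate accuracies — the only reading consistent with CI widths of a
  few tenths of a percent at R = 1000. The inner loop re-ranks features
  only (it does not retrain the SVM per inner fold), matching the
  frequency-of-selection description of the procedure.
* **Nested LOOCV**: the outer loop holds out one sample; the inner loop
  runs plain LOOCV on the remaining N−1 (ranking on N−2 per fold) for each
  candidate signature size k in {5, 10, 15, 20, 25, 30, 40, 50} (a grid
  bracketing the fixed k = 30 of the Monte-Carlo scheme, chosen because the
  procedure's own description leaves the grid open); the
  accuracy-maximizing k (ties → smallest) classifies the outer sample. The
  final signature size is the modal k* (ties → smallest), refit on all
  samples. The scheme is fully deterministic.

Assay comparison (`compare_assays`) is a Welch t-test on the two replicate
accuracy vectors; the original analysis does not name its test, and this
is the declared dialect.

No ranking or standardization ever sees the fold's test portion; the null
calibration tests (accuracy at chance under no planted effect) are the
operational check that no selection bias leaks in.

The heavy cross-validation loops call the libsvm training routine through
scikit-learn's low-level binding rather than constructing an `SVC`
estimator per fold; the solver, tolerances and resulting decision rule are
identical (asserted against `SVC` in the test suite), only the per-call
validation overhead is skipped.

## Robustness and survival

Robustness is concordance — the fraction of condition-varied replicates of
a sample whose call matches the call on that sample's default-condition
(600 ng, RA, FH, 1:50, reference lot) array — because technical replicate
panels mostly lack ground-truth outcomes, so accuracy is undefined there.
Each replicate must vary exactly one covariate.

Kaplan–Meier curves use the product-limit estimator with events processed
before censorings at tied times; with no censoring the curve equals the
empirical survival function. The log-rank test is the unweighted
Mantel–Haenszel statistic, chi² = (ΣO − ΣE)²/ΣV with 1 df; the p-value is
floored at the smallest positive double to respect p ∈ (0, 1].

## Problem sizes and what the tests show

The test suite runs the full pipeline on cohorts of n = 60 samples with
2,500 probe sets — a deliberate desk-scale choice that keeps the complete
suite under a few minutes while leaving every statistical property
measurable (null calibration bands, planted-signature recovery, CI
convergence, robustness patterns over 10 seeds).

Passing tests show that the *procedures* behave correctly on data with the
assumed structure: unbiased cross-validation, correct oracles, the
expected qualitative responses to analytical perturbations. They do not
show that real FFPE cohorts satisfy the model: the generator has no
cross-hybridization, no RNA-degradation kinetics, no spatial artifacts, no
probe-specific affinity beyond the probe-set baseline, Gaussian biology
with a common variance, and an exponential/uniform survival model. Real
prognostic accuracies (and the identity of any real signature) can only be
established on real cohort data.

## Known limitations

* The detection rule is a declared dialect; the vendor QC tool's exact
  algorithm is unpublished, and absolute detection counts depend on it.
* The labeling-kit compression acts around a single global background
  pivot; real compression is probe-dependent.
* `compare_assays` assumes independent replicate accuracy vectors; for
  overlapping cohorts the test is anti-conservative.
* With heavy ties the quantile-normalization tie rule (mean of spanned
  quantiles) intentionally breaks the identical-sorted-vector property.
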