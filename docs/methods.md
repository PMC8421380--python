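# Methods

## PRV statistics and beat filtering

A recording is an ordered series of beat-to-beat pulse intervals (ms),
typically 10–12 beats over ~10 s. Six irregularity statistics are computed
(sARV, RMSSD, SD, CV, relative range, IPP; definitions in the README). Two
independent banding rules, both centred on the mean of the **raw** series and
computed once with no re-estimation:

- **Exclusion pre-filter** (default fraction 0.25, admissible up to 0.30):
  beats deviating more than the fraction from the raw mean are dropped before
  computing sARV/RMSSD/SD/CV/relative range. This suppresses ectopic
  premature/compensatory pairs that would otherwise inflate the statistics in
  non-AF participants. The default 0.25 is the conventional choice in
  cuff-based PRV work; the package exposes it as configuration because the
  optimal value is dataset-dependent.
- **IPP band** (default ±0.15): IPP is the share of *raw* beats outside the
  band. It is deliberately unfiltered — it is itself an outlier-counting
  statistic, and pre-filtering would destroy it.

SD uses the n−1 (sample) denominator: the convention in heart-rate-variability
work and the safer choice at n ≈ 11. A recording with fewer than two surviving
intervals raises a recoverable `InsufficientBeatsError`; pipelines record the
recording as unevaluable and continue. Fewer than 8 raw beats flags a low
pulse rate (< 48 beats/min over ~10 s), carried as `low_beat_flag` for
subgroup analyses. Interval readers reject non-positive or non-numeric values
outright rather than coercing them.

## Synthetic cohort generator

The generator emulates a primary-care AF screening study of 421 patients with
two sequential PRV readings and one single-lead-device (KMCM) label each.
Defaults are the study's empirical margins: AF prevalence 133/421; interval
coefficient of variation 2.1% (non-AF) vs 12.6% (AF); mean heart rate 70 vs
76 beats/min; class-conditional device-label confusion rows
(AF present: 3/111/15/4 of 133 over normal/possible-AF/unclassified/blank;
AF absent: 195/23/57/13 of 288); subgroup-flag frequencies conditional on AF
status (e.g. prior AF diagnosis 124/133 vs 80/288).

Interval model per rhythm class:

- **sinus / af**: i.i.d. gamma intervals with the target mean and CV. Gamma is
  a right-skewed positive family; the (mean, CV) match is the contract, not
  the family. AF intervals are serially independent ("irregularly
  irregular") — the conservative default at ~11 beats.
- **sinus_with_ectopy**: sinus base in which each beat starts a
  premature–compensatory pair (0.6×, 1.4× the base mean) with per-beat
  probability 0.15 — the classic false-positive mechanism. A fraction 36/288
  of non-AF participants get this class (the study's non-paced, non-AF
  arrhythmia margin).
- **af_paced**: near-constant intervals (CV 0.2%) despite AF ground truth —
  a ventricularly paced AF patient, the classic false-negative. Fraction
  7/133 of AF participants.

Series length is however many intervals fit the 10-s recording window
(minimum 2; 10–13 at sinus rates). The second reading is re-drawn from the
same rhythm with its mean interval perturbed by a 2% lognormal jitter,
mimicking the ~95-s gap between sequential measurements rather than re-noising
the first series. One root seed drives everything through per-participant
`SeedSequence` substreams, so cohorts are bit-reproducible and parallelisable.

**What the generator does not emulate.** Real pulse series carry respiratory
sinus arrhythmia, serial correlation in AF, measurement artefacts and
heavy-tailed outliers; device labels in reality depend on the rhythm (ectopy
drives "unclassified"), not only on AF status; paced non-AF participants
(6/288 in the study) have no rhythm class here. Two visible consequences:
the non-AF IPP median is ~0 (clean gamma sinus never leaves a ±15% band, where
the study reports a median of 9.1%), and the five filtered-series statistics
are nearly rank-equivalent across synthetic participants — the discordant
AF/non-AF pairs are dominated by the paced-AF and ectopy records, which all
five statistics misorder identically, so their AUCs coincide on synthetic
cohorts while real data separates them. Passing tests therefore demonstrate
correctness of the estimators and the expected qualitative regime
(AUC ≈ 0.86–0.96, ≥3-fold median separation), not quantitative agreement of
every statistic's AUC with any particular dataset.

## Classification rules

Threshold classification is strict (`value > t`; ties negative), matching the
"had to exceed the threshold" convention. In device fusion, any label other
than "normal" — including unclassified and blank — counts as "did not read
normal": the wording is label-based and blank output is not "normal". The
banded rule treats the **open** interval (lower, upper) as the uncertain zone
requiring confirmation (default: both readings must exceed the threshold);
the open interval makes a degenerate band (lower = upper) reduce exactly to
the first-reading rule, and differs from a closed reading only on the
boundary. Missing required inputs make a prediction *unevaluable* (`None`),
a state distinct from negative; unevaluable records are excluded from metric
denominators and reported separately.

## Device-label evaluation

The 2×4 cross-tab (ECG AF status × label) collapses to a 2×2 under two
policies: `penalise_unreadable` (unclassified/blank deemed incorrect:
false negatives if AF present, false positives if absent) and
`exclude_unreadable` (dropped before the 2×2). Exclusion necessarily
dominates penalisation in sensitivity and specificity. Metrics with zero
denominators are reported as undefined, never 0. Report percentages round
half-up to whole percent, with unrounded proportions retained alongside.
Subgroup analyses filter participant records by their boolean flags before
cross-tabulation.

## Evaluation battery

- **AUC** is computed by the Mann–Whitney identity on midranks (ties ½),
  equivalent to trapezoidal ROC area. The default 95% CI is DeLong's
  structural-components estimator (validated against R's pROC); a seeded
  stratified percentile bootstrap (2000 resamples) is the alternative. The
  study-style reporting rounds AUC to 2 decimals and sens/spec/accuracy to
  whole percent.
- **Repeated cross-validation**: stratified k-fold (both classes in every
  fold by construction), AUC re-estimated on each held-out fold — there is no
  tunable model, so CV exposes sampling variability. Reported: mean fold AUC
  and the 2.5/97.5 percentile interval over the k·reps fold values.
  Fold-level averaging (not pooling) is the default because it produces the
  wide intervals characteristic of small-fold AUC estimation.
- **Decision curves**: the marker is mapped to probabilities by univariate
  logistic calibration with a tiny ridge penalty (λ = 1e-4 on the slope after
  score standardisation). The penalty keeps a single, deterministic code path
  that converges under complete separation and maps separable markers to
  probabilities ≈ 0/1 — preserving the requirement that a perfect marker
  dominates treat-all and treat-none at every interior threshold probability,
  which a quantile-based fallback would violate at prevalences far from the
  threshold. The calibration fit (slope, intercept, convergence) is written
  to the run log. Predictions use `probability ≥ pt`.
- **Precision–recall**: the sweep classifies `score ≥ t` at every achieved
  score; area is the trapezoid over achieved operating points (no
  interpolated precision), anchored at recall 0 with the first point's
  precision so a perfectly separating marker scores exactly 1. The
  prevalence-standardised variant replaces precision pointwise with
  PPV(sens, spec, prevalence) via Bayes' rule; at the cohort's own prevalence
  this reproduces the empirical PPV identically.

## Problem sizes and defaults

The acceptance battery evaluates a 2000-participant synthetic cohort — large
enough that median ratios and AUC are stable to well under the tested margins
while the whole battery runs in seconds. Monte-Carlo generator checks use
10 000 series (dispersion target) and 100 000 label draws (confusion-row
goodness of fit, χ² at α = 0.01). Default threshold grids are per-parameter
score quantiles (25 points); the decision-curve grid is pt = 0.05–0.95.

## Known limitations

Beat detection from pressure waveforms is out of scope — the toolkit begins
at interval series. Frequency-domain variability measures are not included.
The device's internal algorithm is not modelled, only its four output labels.
Clinical risk scores (CHADS₂, CHA₂DS₂-VASc, 5-year AF risk) enter only as
boolean subgroup flags. AUC comparisons between statistics carry no formal
test. The synthetic generator's simplifications above mean per-statistic AUC
differences should not be read off synthetic cohorts.
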