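# prvscreen

Atrial fibrillation (AF) screening from **pulse-rate variability (PRV)**:
irregularity statistics for short beat-interval recordings, fusion with a
single-lead rhythm device, and the full diagnostic-evaluation battery —
plus a synthetic cohort generator so every stage can be exercised and tested
without patient data.

## The problem

AF is the most common cardiac arrhythmia and a major, treatable stroke risk
factor, yet it is often first diagnosed after a stroke. Automatic blood
pressure measurement offers an opportunistic screen: the beat-to-beat timing
of the arterial pulse is *irregularly irregular* in AF, so a ~10-s recording
of 10–12 pulse intervals carries a strong rhythm signal. Hand-held single-lead
ECG devices (e.g. Kardia Mobile, "KMCM") screen for AF too, but return
*unclassified* or blank output for a sizeable share of recordings, and those
unreadable recordings drive most missed cases. This package implements the
analysis toolkit for such a screening study: the PRV statistics, the
device-label evaluation, and strategies that combine the two.

## What it computes

For an interval series $d_1, \dots, d_n$ (ms) with mean $\bar d$:

| statistic | definition |
|---|---|
| sARV | $100 \cdot \mathrm{mean}_i\,\lvert d_{i+1}-d_i\rvert \,/\, \bar d$ (%) |
| RMSSD | $\sqrt{\mathrm{mean}_i\,(d_{i+1}-d_i)^2}$ (ms) |
| SD | sample standard deviation (ms) |
| CV | $100 \cdot \mathrm{SD}/\bar d$ (%), the "irregularity index" |
| relative range | $100 \cdot (\max - \min)/\bar d$ (%) |
| IPP | % of beats with $\lvert d_i - \bar d\rvert > 0.15\,\bar d$ |

sARV/RMSSD/SD/CV/relative range are computed after an ectopy pre-filter that
drops beats deviating more than 25% (configurable up to 30%) from the raw
mean; IPP is computed on the raw series. Evaluation covers ROC/AUC (DeLong or
bootstrap CI), repeated stratified 10×10-fold cross-validated AUC, decision
curves (net benefit $\mathrm{TP}/n - (\mathrm{FP}/n)\,p_t/(1-p_t)$ against
treat-all/treat-none), precision–recall curves with AUPRC,
prevalence-standardised PPV, and 2×4 device-label cross-tab metrics under
explicit policies for unreadable output. Combination rules (mean of two
readings, both readings, PRV + non-normal device label, banded confirmation)
turn one or two readings into a single prediction.

## Worked example

```python
from prvscreen import LabelCrossTab, UnreadablePolicy, build_contingency, diagnostic_metrics

xtab = LabelCrossTab(af_absent=(195, 23, 57, 13), af_present=(3, 111, 15, 4))
m = diagnostic_metrics(build_contingency(xtab, UnreadablePolicy.PENALISE_UNREADABLE))
```

Running `python examples/05_kmcm_crosstab.py` (the counts are a published
421-recording cross-classification of device labels against 12-lead ECG):

```
421 recordings, 89 unreadable, 332 readable

penalise_unreadable: TP 111 FP 93 TN 195 FN 22
  sensitivity 83%  specificity 68%  accuracy 73%
exclude_unreadable: TP 111 FP 23 TN 195 FN 3
  sensitivity 97%  specificity 89%  accuracy 92%

undetected AF cases: 17% of all AF; 68% of those unclassified, 86% unreadable overall
```

Counting unreadable device output as wrong costs 14 points of sensitivity —
the unreadable recordings are responsible for 86% of all missed AF, which is
exactly where an always-available PRV reading complements the device.

The other scripts in `examples/` walk through each capability: computing PRV
statistics (`01`), simulating a cohort (`02`), AUC and cross-validation
(`03`), decision curves (`04`) and combination rules (`06`). The `prvscreen`
command exposes the same stages from the shell
(`prvscreen simulate|prv|classify|evaluate|kmcm-table|run`).

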