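"""Evaluate a single-lead rhythm device from its 2x4 label cross-classification.

The device labels each recording normal / possible AF / unclassified / blank.
Counts below are the published cross-classification of 421 primary-care
recordings against 12-lead-ECG ground truth.  Two policies handle the
unreadable (unclassified/blank) output: penalise it as an error, or exclude it.
"""

from prvscreen import LabelCrossTab, UnreadablePolicy, build_contingency, diagnostic_metrics
from prvscreen.kmcm import round_half_up_pct, undetected_breakdown

xtab = LabelCrossTab(af_absent=(195, 23, 57, 13), af_present=(3, 111, 15, 4))
print(f"{xtab.n_total} recordings, {xtab.n_unreadable} unreadable, {xtab.n_readable} readable\n")

for policy in UnreadablePolicy:
    ct = build_contingency(xtab, policy)
    m = diagnostic_metrics(ct)
    print(f"{policy.value}: TP {ct.tp} FP {ct.fp} TN {ct.tn} FN {ct.fn}")
    print(
        f"  sensitivity {round_half_up_pct(m['sensitivity'])}%  "
        f"specificity {round_half_up_pct(m['specificity'])}%  "
        f"accuracy {round_half_up_pct(m['accuracy'])}%"
    )

b = undetected_breakdown(xtab)
print(
    f"\nundetected AF cases: {round_half_up_pct(b['undetected_fraction'])}% of all AF; "
    f"{round_half_up_pct(b['frac_unclassified_of_undetected'])}% of those unclassified, "
    f"{round_half_up_pct(b['frac_unreadable_of_undetected'])}% unreadable overall"
)
print(
    "\nUnreadable output drives most missed cases — the motivation for pairing"
    "\nthe device with a PRV measurement that always yields a classification."
)
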