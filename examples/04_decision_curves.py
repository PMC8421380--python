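"""Decision-curve analysis: is screening with a PRV marker clinically useful?

Net benefit at threshold probability pt weighs true positives against false
positives at the exchange rate pt/(1-pt).  A useful marker exceeds both the
treat-all and treat-none (zero) reference strategies over the clinically
relevant range of pt.
"""

import numpy as np

from prvscreen import CohortConfig, ScoredCohort, decision_curve, simulate_cohort
from prvscreen.pipeline import compute_cohort_prv, scored_cohort
from prvscreen.prv import BeatFilterConfig

records = simulate_cohort(CohortConfig(n_participants=600, seed=11))
results, _ = compute_cohort_prv(records, BeatFilterConfig())
by_key = {(r.participant_id, r.reading_index): r for r in results}
cohort, _ = scored_cohort(records, by_key, "sarv")

res = decision_curve(cohort, pt_grid=np.round(np.arange(0.1, 0.91, 0.1), 2))
print("pt    sARV marker   treat-all   treat-none")
for pt, nb, nb_all in zip(res.marker.x, res.marker.y, res.treat_all.y):
    print(f"{pt:.1f}   {nb:11.3f}   {nb_all:9.3f}   {0.0:10.3f}")

print(
    "\nA net benefit of 0.1 means 10 more net true positives per 100 patients"
    "\nscreened.  The marker column staying above both references across pt"
    "\nindicates consistent clinical utility of sARV-based screening."
)
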