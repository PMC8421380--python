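"""Compute the six pulse-rate-variability statistics for single recordings.

Two hand-built ~10-beat interval series: a regular sinus-rhythm recording and
an irregularly irregular AF-like recording.  The six statistics quantify
beat-to-beat irregularity; AF typically shows values several-fold higher.
"""

import numpy as np

from prvscreen import BeatFilterConfig, PulseIntervalSeries, compute_prv

sinus = PulseIntervalSeries(
    "example-sinus", 1,
    np.array([857, 840, 865, 851, 844, 860, 849, 855, 846, 852, 858], float),
)
af = PulseIntervalSeries(
    "example-af", 1,
    np.array([620, 910, 745, 1050, 680, 890, 560, 980, 820, 700, 930], float),
)

for series in (sinus, af):
    r = compute_prv(series, BeatFilterConfig())
    print(f"{series.participant_id}:")
    print(f"  sARV {r.sarv:6.2f} %   RMSSD {r.rmssd:6.1f} ms   SD {r.sd:6.1f} ms")
    print(f"  CV   {r.cv:6.2f} %   rel. range {r.relative_range:6.1f} %   IPP {r.ipp:5.1f} %")
    print(f"  beats: {r.n_beats_used}/{r.n_beats_raw} kept by the 25% exclusion filter")

print(
    "\nThe AF-like recording shows ~5-10x higher irregularity on every statistic;"
    "\nthresholding any of them (e.g. sARV > 6%) yields a screening classifier."
)
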