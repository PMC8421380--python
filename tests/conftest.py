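import numpy as np
import pytest

from prvscreen.cohort import CohortConfig, simulate_cohort
from prvscreen.pipeline import compute_cohort_prv, scored_cohort
from prvscreen.prv import BeatFilterConfig


@pytest.fixture(scope="session")
def default_cohort_2000():
    """A default-calibration synthetic cohort of 2000 participants with PRV values.

    Session-scoped: the separation/discrimination checks and the acceptance
    battery all evaluate the same study conditions.
    """
    records = simulate_cohort(CohortConfig(n_participants=2000, seed=20260925))
    results, failures = compute_cohort_prv(records, BeatFilterConfig())
    assert not failures
    by_key = {(r.participant_id, r.reading_index): r for r in results}
    return records, by_key


@pytest.fixture(scope="session")
def scored(default_cohort_2000):
    """parameter -> ScoredCohort (first reading) on the default synthetic cohort."""
    records, by_key = default_cohort_2000

    def _get(parameter, use_mean_of_two=False):
        cohort, skipped = scored_cohort(
            records, by_key, parameter, use_mean_of_two=use_mean_of_two
        )
        assert not skipped
        return cohort

    return _get
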