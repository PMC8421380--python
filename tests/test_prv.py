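"""PRV statistics: worked examples, filtering rules, and structural properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prvscreen.prv import (
    BeatFilterConfig,
    InsufficientBeatsError,
    PulseIntervalSeries,
    compute_prv,
    cv,
    filter_beats,
    ipp,
    relative_range,
    rmssd,
    sarv,
    sd,
)

intervals_strategy = st.lists(
    st.floats(min_value=300.0, max_value=2000.0, allow_nan=False), min_size=2, max_size=20
).map(lambda xs: np.asarray(xs))


def series(iv, pid="p", ridx=1):
    return PulseIntervalSeries(pid, ridx, np.asarray(iv, dtype=float))


# --- naive reference implementations: plain loops, no shared code paths ---

def naive_sarv(iv):
    diffs = [abs(iv[i + 1] - iv[i]) for i in range(len(iv) - 1)]
    return 100.0 * (sum(diffs) / len(diffs)) / (sum(iv) / len(iv))


def naive_rmssd(iv):
    sq = [(iv[i + 1] - iv[i]) ** 2 for i in range(len(iv) - 1)]
    return math.sqrt(sum(sq) / len(sq))


def naive_sd(iv):
    m = sum(iv) / len(iv)
    return math.sqrt(sum((x - m) ** 2 for x in iv) / (len(iv) - 1))


def naive_cv(iv):
    return 100.0 * naive_sd(iv) / (sum(iv) / len(iv))


def naive_relative_range(iv):
    return 100.0 * (max(iv) - min(iv)) / (sum(iv) / len(iv))


def naive_ipp(iv, frac=0.15):
    m = sum(iv) / len(iv)
    return 100.0 * sum(1 for x in iv if abs(x - m) > frac * m) / len(iv)


NAIVE = {
    sarv: naive_sarv, rmssd: naive_rmssd, sd: naive_sd,
    cv: naive_cv, relative_range: naive_relative_range, ipp: naive_ipp,
}


class TestBeatFilter:
    def test_excludes_beats_outside_band_of_raw_mean(self):
        out = filter_beats(series([800, 800, 800, 1200]), 0.25)
        np.testing.assert_array_equal(out.intervals, [800, 800, 800])

    def test_constant_series_untouched(self):
        out = filter_beats(series([800, 800, 800]), 0.25)
        np.testing.assert_array_equal(out.intervals, [800, 800, 800])

    def test_wider_band_keeps_alternating_series(self):
        out = filter_beats(series([700, 900, 700]), 0.30)
        np.testing.assert_array_equal(out.intervals, [700, 900, 700])

    def test_order_preserved(self):
        # raw mean 1031.4; the 30% band [722.0, 1340.9] drops only the 2400 beat
        out = filter_beats(series([800, 820, 790, 810, 2400, 805, 795]), 0.30)
        np.testing.assert_array_equal(out.intervals, [800, 820, 790, 810, 805, 795])

    def test_insufficient_survivors_raise(self):
        with pytest.raises(InsufficientBeatsError):
            filter_beats(series([100, 2000]), 0.25)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_beats(series([800, 900]), 0.0)


@pytest.mark.parametrize(
    "func, iv, expected",
    [
        (sarv, [700, 900, 700], 100 * 200 / (2300 / 3)),
        (rmssd, [700, 900, 700], 200.0),
        (sd, [700, 900, 700], math.sqrt(40000 / 3)),
        (cv, [700, 900, 700], 100 * math.sqrt(40000 / 3) / (2300 / 3)),
        (relative_range, [700, 900, 700], 100 * 200 / (2300 / 3)),
        (ipp, [800, 800, 800, 1000], 25.0),
        (ipp, [600, 1000], 100.0),
    ],
)
def test_worked_examples(func, iv, expected):
    assert func(np.asarray(iv, dtype=float)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("func", [sarv, rmssd, sd, cv, relative_range, ipp])
def test_constant_series_gives_zero(func):
    assert func(np.full(10, 850.0)) == 0.0


@pytest.mark.parametrize("func", [sarv, rmssd, sd, cv, relative_range])
def test_too_few_intervals_raise(func):
    with pytest.raises(InsufficientBeatsError):
        func(np.array([800.0]))


class TestSeriesValidation:
    @pytest.mark.parametrize("bad", [[800.0], []])
    def test_short_series_rejected(self, bad):
        with pytest.raises(InsufficientBeatsError):
            series(bad)

    @pytest.mark.parametrize("bad", [[800, -5], [800, 0], [800, np.nan]])
    def test_nonpositive_or_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            series(bad)


class TestComputePrv:
    def test_filtered_to_constant_but_ipp_sees_raw_outlier(self):
        r = compute_prv(series([800, 800, 800, 1200]))
        assert (r.sarv, r.rmssd, r.sd, r.cv, r.relative_range) == (0, 0, 0, 0, 0)
        # raw mean 900, +/-15% band [765, 1035]: only the 1200 beat is irregular
        assert r.ipp == pytest.approx(25.0)
        assert (r.n_beats_raw, r.n_beats_used) == (4, 3)

    @pytest.mark.parametrize("n, flag", [(10, False), (6, True), (8, False)])
    def test_low_beat_flag_counts_raw_beats(self, n, flag):
        r = compute_prv(series([850.0] * n))
        assert r.low_beat_flag is flag
        assert all(
            getattr(r, f) == 0 for f in ("sarv", "rmssd", "sd", "cv", "relative_range", "ipp")
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BeatFilterConfig(exclusion_fraction=1.5)
        with pytest.raises(ValueError):
            BeatFilterConfig(ipp_fraction=0.0)


@settings(max_examples=100, derandomize=True)
@given(iv=intervals_strategy, k=st.floats(min_value=0.1, max_value=10.0))
def test_scale_invariance_and_linearity(iv, k):
    """Ratio statistics are scale-free; SD and RMSSD scale linearly with k."""
    for func in (sarv, cv, relative_range, ipp):
        assert func(iv * k) == pytest.approx(func(iv), rel=1e-9, abs=1e-9)
    assert rmssd(iv * k) == pytest.approx(k * rmssd(iv), rel=1e-9)
    assert sd(iv * k) == pytest.approx(k * sd(iv), rel=1e-9)


@settings(max_examples=100, derandomize=True)
@given(iv=intervals_strategy)
def test_rmssd_dominates_mean_absolute_successive_difference(iv):
    """Quadratic mean >= arithmetic mean of |successive differences|."""
    assert 100.0 * rmssd(iv) / iv.mean() >= sarv(iv) - 1e-9


def test_permutation_sensitivity():
    """sd/cv/relative_range/ipp ignore order; sarv and rmssd do not."""
    a = np.array([700.0, 750, 800, 850, 900, 1100])
    b = np.array([700.0, 900, 750, 1100, 800, 850])
    for func in (sd, cv, relative_range, ipp):
        assert func(a) == pytest.approx(func(b))
    assert sarv(a) != pytest.approx(sarv(b))
    assert rmssd(a) != pytest.approx(rmssd(b))


def test_statistics_match_naive_oracles_on_random_series():
    """Each statistic agrees with an independent loop implementation (1e-9 rel)."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = rng.integers(2, 16)
        iv = rng.uniform(300, 1800, size=n)
        for func, oracle in NAIVE.items():
            assert func(iv) == pytest.approx(oracle(list(iv)), rel=1e-9, abs=1e-12)
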