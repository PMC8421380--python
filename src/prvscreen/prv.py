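"""Pulse-rate-variability (PRV) statistics for short beat-interval recordings.

A single automated blood-pressure measurement yields roughly 10-12 beat-to-beat
pulse intervals over ~10 s.  Six irregularity statistics are computed from such
a series to discriminate atrial fibrillation (irregularly irregular intervals)
from sinus rhythm:

1. sARV  - standardised average real variability: mean absolute successive
   difference as a percentage of the mean interval.
2. RMSSD - root mean square of successive differences (ms).
3. SD    - sample standard deviation of the intervals (ms).
4. CV    - coefficient of variation ("irregularity index"): SD as a percentage
   of the mean interval.
5. Relative range - (max - min) / mean, as a percentage.
6. IPP   - irregular pulse percentage: share of beats deviating more than
   +/-15% from the mean beat duration.

Statistics 1-5 are computed after an ectopy pre-filter that drops beats whose
duration differs from the raw-series mean by more than a configurable fraction
(default 25%); IPP is computed on the raw, unfiltered series.  Both bands are
centred on the mean of the raw series, computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

__all__ = [
    "InsufficientBeatsError",
    "PulseIntervalSeries",
    "BeatFilterConfig",
    "PRVResult",
    "filter_beats",
    "sarv",
    "rmssd",
    "sd",
    "cv",
    "relative_range",
    "ipp",
    "compute_prv",
    "PRV_PARAMETERS",
]

#: canonical statistic names, used as column names throughout the package
PRV_PARAMETERS = ("sarv", "rmssd", "sd", "cv", "relative_range", "ipp")

#: fewer raw beats than this flags a low pulse rate (< 48 beats/min over ~10 s)
LOW_BEAT_COUNT = 8


class InsufficientBeatsError(ValueError):
    """Raised when a recording has too few (surviving) intervals.

    This is a recoverable, per-recording condition: pipelines catch it, record
    the recording as unevaluable and continue with the rest of the cohort.
    """


@dataclass(frozen=True)
class PulseIntervalSeries:
    """One recording's ordered beat-to-beat intervals in milliseconds.

    Order is acquisition order; successive-difference statistics depend on it.
    """

    participant_id: str
    reading_index: int
    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1 or iv.size < 2:
            raise InsufficientBeatsError(
                f"series ({self.participant_id!r}, reading {self.reading_index}) "
                f"needs >= 2 intervals, got {iv.size}"
            )
        if not np.all(np.isfinite(iv)) or np.any(iv <= 0):
            raise ValueError(
                f"series ({self.participant_id!r}, reading {self.reading_index}) "
                "contains non-positive or non-finite intervals"
            )
        iv.setflags(write=False)
        object.__setattr__(self, "intervals", iv)

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class BeatFilterConfig:
    """Beat-exclusion and irregularity-band settings.

    ``exclusion_fraction`` drops beats more than that fraction away from the
    raw mean before computing sARV/RMSSD/SD/CV/relative range (admissible
    0.25-0.30 in practice).  ``ipp_fraction`` is the +/- band defining an
    "irregular" pulse for IPP.  The two rules are independent.
    """

    exclusion_fraction: float = 0.25
    ipp_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in ("exclusion_fraction", "ipp_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass(frozen=True)
class PRVResult:
    """The six PRV statistics plus beat-filtering bookkeeping for one recording."""

    participant_id: str
    reading_index: int
    sarv: float  # percent
    rmssd: float  # ms
    sd: float  # ms
    cv: float  # percent
    relative_range: float  # percent
    ipp: float  # percent
    n_beats_raw: int
    n_beats_used: int
    low_beat_flag: bool

    def value(self, parameter: str) -> float:
        if parameter not in PRV_PARAMETERS:
            raise KeyError(f"unknown PRV parameter {parameter!r}")
        return getattr(self, parameter)


ArrayLike = Union[PulseIntervalSeries, np.ndarray, Iterable[float]]


def _as_intervals(series: ArrayLike, minimum: int = 2) -> np.ndarray:
    if isinstance(series, PulseIntervalSeries):
        iv = series.intervals
    else:
        iv = np.asarray(series, dtype=float)
    if iv.size < minimum:
        raise InsufficientBeatsError(
            f"need >= {minimum} intervals, got {iv.size}"
        )
    return iv


def filter_beats(
    series: PulseIntervalSeries, exclusion_fraction: float = 0.25
) -> PulseIntervalSeries:
    """Drop beats more than ``exclusion_fraction`` away from the raw mean.

    The band is centred on the mean of the *raw* series, computed once (no
    iterative re-estimation).  Order is preserved.  Raises
    :class:`InsufficientBeatsError` if fewer than two intervals survive.
    """
    if not (0.0 < exclusion_fraction <= 1.0):
        raise ValueError("exclusion_fraction must lie in (0, 1]")
    iv = series.intervals
    m = iv.mean()
    keep = np.abs(iv - m) <= exclusion_fraction * m
    if keep.sum() < 2:
        raise InsufficientBeatsError(
            f"series ({series.participant_id!r}, reading {series.reading_index}): "
            f"only {int(keep.sum())} beats survive the exclusion filter"
        )
    return PulseIntervalSeries(
        participant_id=series.participant_id,
        reading_index=series.reading_index,
        intervals=iv[keep],
    )


def sarv(series: ArrayLike) -> float:
    """Mean absolute successive difference as a percentage of the mean interval."""
    iv = _as_intervals(series)
    return 100.0 * np.abs(np.diff(iv)).mean() / iv.mean()


def rmssd(series: ArrayLike) -> float:
    """Root mean square of successive interval differences, in ms."""
    iv = _as_intervals(series)
    return float(np.sqrt(np.mean(np.diff(iv) ** 2)))


def sd(series: ArrayLike) -> float:
    """Sample standard deviation (n - 1 denominator) of the intervals, in ms."""
    iv = _as_intervals(series)
    return float(np.std(iv, ddof=1))


def cv(series: ArrayLike) -> float:
    """Coefficient of variation: sample SD as a percentage of the mean interval."""
    iv = _as_intervals(series)
    return 100.0 * np.std(iv, ddof=1) / iv.mean()


def relative_range(series: ArrayLike) -> float:
    """(max - min) interval divided by the mean, as a percentage."""
    iv = _as_intervals(series)
    return 100.0 * (iv.max() - iv.min()) / iv.mean()


def ipp(series: ArrayLike, ipp_fraction: float = 0.15) -> float:
    """Percentage of beats deviating more than ``ipp_fraction`` from the raw mean.

    Applied to the raw, unfiltered series: the exclusion pre-filter covers only
    the other five statistics.
    """
    if not (0.0 < ipp_fraction <= 1.0):
        raise ValueError("ipp_fraction must lie in (0, 1]")
    iv = _as_intervals(series, minimum=1)
    m = iv.mean()
    irregular = np.abs(iv - m) > ipp_fraction * m
    return 100.0 * irregular.mean()


def compute_prv(
    series: PulseIntervalSeries, config: BeatFilterConfig = BeatFilterConfig()
) -> PRVResult:
    """Compute all six PRV statistics for one recording.

    sARV/RMSSD/SD/CV/relative range use the exclusion-filtered series; IPP uses
    the raw series.  Raises :class:`InsufficientBeatsError` when fewer than two
    beats survive filtering.
    """
    filtered = filter_beats(series, config.exclusion_fraction)
    iv = filtered.intervals
    return PRVResult(
        participant_id=series.participant_id,
        reading_index=series.reading_index,
        sarv=sarv(iv),
        rmssd=rmssd(iv),
        sd=sd(iv),
        cv=cv(iv),
        relative_range=relative_range(iv),
        ipp=ipp(series.intervals, config.ipp_fraction),
        n_beats_raw=len(series),
        n_beats_used=len(filtered),
        low_beat_flag=len(series) < LOW_BEAT_COUNT,
    )
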