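"""Synthetic primary-care AF screening cohorts.

The study population this generator emulates is a primary-care sample of 421
patients, 133 of whom had ECG-confirmed atrial fibrillation (AF).  Each
participant contributes two sequential ~10-s pulse-interval recordings, an ECG
ground-truth label, arrhythmia/pacing/subgroup flags and a single-lead-device
(KMCM) rhythm label drawn from {normal, possible_af, unclassified, blank}.

Rhythm classes and their interval models:

- ``sinus``: i.i.d. gamma intervals, mean 60000/HR ms, coefficient of
  variation ~2.1% (the non-AF median CV of the study population).
- ``af``: same family with CV ~12.6% — irregularly irregular, serially
  independent.
- ``sinus_with_ectopy``: sinus base with premature-compensatory beat pairs
  (0.6x / 1.4x the base mean), the classic false-positive mechanism.
- ``af_paced``: near-constant intervals (CV <= 0.5%) despite AF ground truth —
  a ventricularly paced AF patient, the classic false-negative mechanism.

All randomness flows from one root seed through per-participant substreams
(:class:`numpy.random.SeedSequence` spawning), so cohorts are reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .kmcm import KMCM_LABELS, KmcmLabel
from .prv import PulseIntervalSeries

__all__ = [
    "RhythmClass",
    "CohortConfig",
    "ParticipantRecord",
    "gen_intervals",
    "simulate_kmcm_label",
    "simulate_cohort",
]


class RhythmClass(str, enum.Enum):
    SINUS = "sinus"
    AF = "af"
    SINUS_WITH_ECTOPY = "sinus_with_ectopy"
    AF_PACED = "af_paced"

    @property
    def is_af(self) -> bool:
        return self in (RhythmClass.AF, RhythmClass.AF_PACED)


def _row(*counts: float) -> Tuple[float, ...]:
    total = float(sum(counts))
    return tuple(c / total for c in counts)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults reproduce the study cohort's margins.

    KMCM confusion rows are probabilities over (normal, possible_af,
    unclassified, blank), conditional on ECG AF status; defaults are the
    study's empirical proportions (AF present 3/111/15/4 of 133, AF absent
    195/23/57/13 of 288).  Subgroup flag frequencies are likewise the study's
    class-conditional margins.
    """

    n_participants: int = 421
    af_prevalence: float = 133 / 421
    sinus_cv_pct: float = 2.1
    af_cv_pct: float = 12.6
    paced_cv_pct: float = 0.2
    mean_hr_sinus: float = 70.0
    mean_hr_af: float = 76.0
    ectopy_rate: float = 0.15  # per-beat probability of a premature-compensatory pair
    ectopy_fraction_nonaf: float = 36 / 288  # non-AF participants with ectopic rhythm
    paced_fraction_of_af: float = 7 / 133
    recording_duration_s: float = 10.0
    n_readings: int = 2
    inter_reading_jitter: float = 0.02  # relative sd of the 2nd reading's mean interval
    kmcm_confusion_af: Tuple[float, float, float, float] = _row(3, 111, 15, 4)
    kmcm_confusion_nonaf: Tuple[float, float, float, float] = _row(195, 23, 57, 13)
    prior_af_given_af: float = 124 / 133
    prior_af_given_nonaf: float = 80 / 288
    age65_given_af: float = 314 / 421
    age65_given_nonaf: float = 314 / 421
    risk5_given_af: float = 71 / 133
    risk5_given_nonaf: float = 185 / 288
    chads2_given_af: float = 84 / 133
    chads2_given_nonaf: float = 219 / 288
    vasc_given_af: float = 130 / 133
    vasc_given_nonaf: float = 274 / 288
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.recording_duration_s <= 0 or self.mean_hr_sinus <= 0 or self.mean_hr_af <= 0:
            raise ValueError("durations and rates must be positive")
        for name in (
            "af_prevalence",
            "ectopy_rate",
            "ectopy_fraction_nonaf",
            "paced_fraction_of_af",
            "prior_af_given_af",
            "prior_af_given_nonaf",
            "age65_given_af",
            "age65_given_nonaf",
            "risk5_given_af",
            "risk5_given_nonaf",
            "chads2_given_af",
            "chads2_given_nonaf",
            "vasc_given_af",
            "vasc_given_nonaf",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("sinus_cv_pct", "af_cv_pct", "paced_cv_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("kmcm_confusion_af", "kmcm_confusion_nonaf"):
            row = getattr(self, name)
            if len(row) != 4 or any(p < 0 for p in row) or abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 4 non-negative probabilities summing to 1")
        if self.n_readings not in (1, 2):
            raise ValueError("n_readings must be 1 or 2")


@dataclass(frozen=True)
class ParticipantRecord:
    """ECG ground truth, flags, device label and PRV readings for one participant."""

    participant_id: str
    ecg_af: bool
    rhythm: RhythmClass
    non_af_arrhythmia: bool
    paced: bool
    prior_af_diagnosis: bool
    age_ge_65: bool
    af_risk_ge_5pct: bool
    high_chads2: bool
    high_cha2ds2vasc: bool
    kmcm_label: KmcmLabel
    readings: Tuple[PulseIntervalSeries, ...]

    def __post_init__(self) -> None:
        if not self.readings:
            raise ValueError(f"{self.participant_id}: at least one reading required")
        ids = {r.participant_id for r in self.readings}
        if ids != {self.participant_id}:
            raise ValueError(f"{self.participant_id}: readings carry foreign participant ids {ids}")
        idx = [r.reading_index for r in self.readings]
        if len(set(idx)) != len(idx):
            raise ValueError(f"{self.participant_id}: duplicate reading_index values {idx}")


def _interval_draw(mean_ms: float, cv_pct: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. positive intervals with given mean and coefficient of variation.

    Gamma is used as the right-skewed positive family; matching the (mean, CV)
    target is the contract, not the family itself.
    """
    if cv_pct <= 0:
        return np.full(size, mean_ms)
    c = cv_pct / 100.0
    shape = 1.0 / c**2
    return rng.gamma(shape, mean_ms * c**2, size=size)


def gen_intervals(
    rhythm: RhythmClass,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    participant_id: str = "synthetic",
    reading_index: int = 1,
    mean_scale: float = 1.0,
) -> PulseIntervalSeries:
    """Generate one recording's pulse-interval series for a rhythm class.

    The series contains as many intervals as fit in ``recording_duration_s``
    (always at least 2).  ``mean_scale`` perturbs the rhythm's mean interval,
    used for the second sequential reading.
    """
    if rhythm in (RhythmClass.AF, RhythmClass.AF_PACED):
        hr = config.mean_hr_af
    else:
        hr = config.mean_hr_sinus
    mean_ms = mean_scale * 60_000.0 / hr
    cv_pct = {
        RhythmClass.SINUS: config.sinus_cv_pct,
        RhythmClass.SINUS_WITH_ECTOPY: config.sinus_cv_pct,
        RhythmClass.AF: config.af_cv_pct,
        RhythmClass.AF_PACED: config.paced_cv_pct,
    }[rhythm]

    duration_ms = config.recording_duration_s * 1000.0
    n_draw = int(np.ceil(duration_ms / mean_ms)) + 8
    iv = _interval_draw(mean_ms, cv_pct, n_draw, rng)

    if rhythm is RhythmClass.SINUS_WITH_ECTOPY:
        i = 0
        while i < iv.size - 1:
            if rng.random() < config.ectopy_rate:
                iv[i] = 0.6 * mean_ms
                iv[i + 1] = 1.4 * mean_ms
                i += 2
            else:
                i += 1

    n_fit = int(np.searchsorted(np.cumsum(iv), duration_ms))
    n_fit = max(2, n_fit)
    return PulseIntervalSeries(
        participant_id=participant_id,
        reading_index=reading_index,
        intervals=iv[:n_fit],
    )


def simulate_kmcm_label(
    rhythm: RhythmClass,
    ecg_af: bool,
    config: CohortConfig,
    rng: np.random.Generator,
) -> KmcmLabel:
    """Draw a device label from the class-conditional confusion distribution.

    Conditioning is on ECG AF status; ``rhythm`` is accepted for future
    refinement (e.g. more unclassified output under ectopy) but unused by the
    default model.
    """
    row = config.kmcm_confusion_af if ecg_af else config.kmcm_confusion_nonaf
    return KMCM_LABELS[rng.choice(4, p=np.asarray(row, dtype=float))]


def _assign_rhythm(ecg_af: bool, config: CohortConfig, rng: np.random.Generator) -> RhythmClass:
    if ecg_af:
        if rng.random() < config.paced_fraction_of_af:
            return RhythmClass.AF_PACED
        return RhythmClass.AF
    if rng.random() < config.ectopy_fraction_nonaf:
        return RhythmClass.SINUS_WITH_ECTOPY
    return RhythmClass.SINUS


def simulate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate a reproducible cohort of :class:`ParticipantRecord`.

    AF status is Bernoulli(``af_prevalence``); each participant gets
    ``n_readings`` sequential recordings, the second re-drawn from the same
    rhythm with its mean interval perturbed by ``inter_reading_jitter``
    (mimicking the ~95 s gap between readings).  Subgroup flags are drawn with
    the study's marginal frequencies conditional on AF status.
    """
    config.__post_init__()  # re-validate in case of replace()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)
    width = max(4, len(str(config.n_participants)))

    records: list[ParticipantRecord] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:0{width}d}"
        ecg_af = bool(rng.random() < config.af_prevalence)
        rhythm = _assign_rhythm(ecg_af, config, rng)

        readings = []
        for ridx in range(1, config.n_readings + 1):
            scale = 1.0 if ridx == 1 else float(
                np.exp(rng.normal(0.0, config.inter_reading_jitter))
            )
            readings.append(
                gen_intervals(
                    rhythm, config, rng,
                    participant_id=pid, reading_index=ridx, mean_scale=scale,
                )
            )

        if ecg_af:
            p_prior, p_age = config.prior_af_given_af, config.age65_given_af
            p_risk, p_ch, p_va = (
                config.risk5_given_af, config.chads2_given_af, config.vasc_given_af,
            )
        else:
            p_prior, p_age = config.prior_af_given_nonaf, config.age65_given_nonaf
            p_risk, p_ch, p_va = (
                config.risk5_given_nonaf, config.chads2_given_nonaf, config.vasc_given_nonaf,
            )

        records.append(
            ParticipantRecord(
                participant_id=pid,
                ecg_af=ecg_af,
                rhythm=rhythm,
                non_af_arrhythmia=rhythm is RhythmClass.SINUS_WITH_ECTOPY,
                paced=rhythm is RhythmClass.AF_PACED,
                prior_af_diagnosis=bool(rng.random() < p_prior),
                age_ge_65=bool(rng.random() < p_age),
                af_risk_ge_5pct=bool(rng.random() < p_risk),
                high_chads2=bool(rng.random() < p_ch),
                high_cha2ds2vasc=bool(rng.random() < p_va),
                kmcm_label=simulate_kmcm_label(rhythm, ecg_af, config, rng),
                readings=tuple(readings),
            )
        )
    return records
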