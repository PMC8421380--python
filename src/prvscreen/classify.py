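"""Binary AF predictions from PRV values, alone or fused with a device label.

A single-threshold classifier flags AF when a PRV statistic strictly exceeds
the threshold ("had to exceed" — ties are negative).  Combination strategies
raise confidence in a positive call by requiring agreement between the two
sequential readings, or between a reading and the single-lead-device (KMCM)
label, where any label other than "normal" (including unclassified and blank
output) counts as "did not read normal".

A prediction is *unevaluable* (returned as ``None``) when an input the rule
requires is missing — e.g. a recording with insufficient beats, or KMCM fusion
without a device label.  Unevaluable predictions are excluded from metric
denominators and counted separately in reports.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .kmcm import KmcmLabel

__all__ = ["CombinationRule", "BandConfig", "classify_single", "classify_combined"]


class CombinationRule(str, enum.Enum):
    FIRST_ONLY = "first_only"
    MEAN_OF_TWO = "mean_of_two"
    BOTH_EXCEED = "both_exceed"
    FIRST_AND_KMCM = "first_and_kmcm"
    MEAN_AND_KMCM = "mean_and_kmcm"
    BANDED = "banded"

    @property
    def needs_second_reading(self) -> bool:
        return self in (CombinationRule.MEAN_OF_TWO, CombinationRule.BOTH_EXCEED,
                        CombinationRule.MEAN_AND_KMCM)

    @property
    def needs_kmcm(self) -> bool:
        return self in (CombinationRule.FIRST_AND_KMCM, CombinationRule.MEAN_AND_KMCM)


@dataclass(frozen=True)
class BandConfig:
    """Uncertainty band for the banded rule.

    First readings inside the open interval (lower, upper) are "uncertain" and
    must be confirmed by a second rule; readings outside it are classified by
    the first reading alone.  Defaults bracket sARV 6-14%, the zone where
    combining measurements pays off.
    """

    parameter: str = "sarv"
    lower: float = 6.0
    upper: float = 14.0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("band requires lower <= upper")


def _missing(value: Optional[float]) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def classify_single(value: Optional[float], threshold: float) -> Optional[bool]:
    """True iff ``value`` strictly exceeds ``threshold``; None if unevaluable."""
    if _missing(value):
        return None
    return bool(value > threshold)


def classify_combined(
    r1: Optional[float],
    r2: Optional[float] = None,
    kmcm_label: Optional[KmcmLabel] = None,
    *,
    rule: CombinationRule = CombinationRule.FIRST_ONLY,
    threshold: float,
    band: Optional[BandConfig] = None,
    confirm_rule: CombinationRule = CombinationRule.BOTH_EXCEED,
) -> Optional[bool]:
    """Evaluate one combination strategy; ``None`` marks an unevaluable record.

    ``banded`` uses the first reading alone when it falls outside the
    uncertainty band, and otherwise defers to ``confirm_rule`` (default: both
    readings must exceed the threshold).
    """
    rule = CombinationRule(rule)

    if rule is CombinationRule.BANDED:
        if band is None:
            raise ValueError("banded rule requires a BandConfig")
        if confirm_rule is CombinationRule.BANDED:
            raise ValueError("confirm_rule may not itself be banded")
        if _missing(r1):
            return None
        if band.lower < r1 < band.upper:
            return classify_combined(
                r1, r2, kmcm_label, rule=confirm_rule, threshold=threshold,
            )
        return classify_single(r1, threshold)

    if _missing(r1):
        return None
    if rule.needs_second_reading and _missing(r2):
        return None
    if rule.needs_kmcm and kmcm_label is None:
        return None

    not_normal = kmcm_label is not None and KmcmLabel(kmcm_label) is not KmcmLabel.NORMAL

    if rule is CombinationRule.FIRST_ONLY:
        return bool(r1 > threshold)
    if rule is CombinationRule.MEAN_OF_TWO:
        return bool((r1 + r2) / 2.0 > threshold)
    if rule is CombinationRule.BOTH_EXCEED:
        return bool(r1 > threshold and r2 > threshold)
    if rule is CombinationRule.FIRST_AND_KMCM:
        return bool(r1 > threshold and not_normal)
    if rule is CombinationRule.MEAN_AND_KMCM:
        return bool((r1 + r2) / 2.0 > threshold and not_normal)
    raise ValueError(f"unhandled rule {rule}")  # pragma: no cover
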