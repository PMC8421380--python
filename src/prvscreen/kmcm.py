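"""Diagnostic evaluation of categorical single-lead-device (KMCM) output.

The device emits one of four labels per recording: "normal", "possible AF",
"unclassified" (insufficient confidence, or regular rhythm outside 50-100
beats/min) or blank (no analysis obtained).  Against ECG ground truth this
yields a 2x4 cross-classification; a binary contingency table follows under an
explicit policy for the unreadable (unclassified/blank) output:

- ``penalise_unreadable``: unreadable recordings count against the device
  (false negative if AF present, false positive if absent).
- ``exclude_unreadable``: unreadable recordings are dropped before the 2x2 is
  formed.

Sensitivity/specificity/accuracy under ``exclude_unreadable`` always dominate
the penalised versions, since unreadable records only ever count as errors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .cohort import ParticipantRecord

__all__ = [
    "KmcmLabel",
    "KMCM_LABELS",
    "UnreadablePolicy",
    "LabelCrossTab",
    "ContingencyTable",
    "build_contingency",
    "diagnostic_metrics",
    "undetected_breakdown",
    "round_half_up_pct",
    "crosstab_report",
]


class KmcmLabel(str, enum.Enum):
    NORMAL = "normal"
    POSSIBLE_AF = "possible_af"
    UNCLASSIFIED = "unclassified"
    BLANK = "blank"


#: fixed column order for cross-tabs and serialisation
KMCM_LABELS: Tuple[KmcmLabel, ...] = (
    KmcmLabel.NORMAL,
    KmcmLabel.POSSIBLE_AF,
    KmcmLabel.UNCLASSIFIED,
    KmcmLabel.BLANK,
)

#: labels that convey no usable rhythm classification
UNREADABLE = (KmcmLabel.UNCLASSIFIED, KmcmLabel.BLANK)


class UnreadablePolicy(str, enum.Enum):
    PENALISE_UNREADABLE = "penalise_unreadable"
    EXCLUDE_UNREADABLE = "exclude_unreadable"


@dataclass(frozen=True)
class LabelCrossTab:
    """Counts indexed by ECG AF status x device label.

    ``af_absent`` / ``af_present`` are 4-tuples of non-negative counts in the
    label order (normal, possible_af, unclassified, blank).
    """

    af_absent: Tuple[int, int, int, int]
    af_present: Tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for name in ("af_absent", "af_present"):
            row = getattr(self, name)
            if len(row) != 4 or any((c < 0 or c != int(c)) for c in row):
                raise ValueError(f"{name} must be 4 non-negative integer counts")
            object.__setattr__(self, name, tuple(int(c) for c in row))

    @classmethod
    def from_records(cls, records: Iterable["ParticipantRecord"]) -> "LabelCrossTab":
        absent = [0, 0, 0, 0]
        present = [0, 0, 0, 0]
        pos = {lab: j for j, lab in enumerate(KMCM_LABELS)}
        for r in records:
            (present if r.ecg_af else absent)[pos[KmcmLabel(r.kmcm_label)]] += 1
        return cls(af_absent=tuple(absent), af_present=tuple(present))

    def count(self, ecg_af: bool, label: KmcmLabel) -> int:
        row = self.af_present if ecg_af else self.af_absent
        return row[KMCM_LABELS.index(label)]

    @property
    def n_total(self) -> int:
        return sum(self.af_absent) + sum(self.af_present)

    @property
    def n_unreadable(self) -> int:
        return sum(self.count(af, lab) for af in (False, True) for lab in UNREADABLE)

    @property
    def n_readable(self) -> int:
        return self.n_total - self.n_unreadable


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/TN/FN counts under a stated unreadable-output policy."""

    tp: int
    fp: int
    tn: int
    fn: int
    policy: Optional[UnreadablePolicy] = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def build_contingency(xtab: LabelCrossTab, policy: UnreadablePolicy) -> ContingencyTable:
    """Collapse a 2x4 label cross-tab to a 2x2 contingency table.

    Under ``penalise_unreadable`` a "possible AF" label is the only true
    positive and a "normal" label the only true negative; unclassified/blank
    recordings are deemed incorrect.  Under ``exclude_unreadable`` those
    columns are dropped first.
    """
    policy = UnreadablePolicy(policy)
    nrm_a, pos_a, unc_a, blk_a = xtab.af_absent
    nrm_p, pos_p, unc_p, blk_p = xtab.af_present
    if policy is UnreadablePolicy.PENALISE_UNREADABLE:
        return ContingencyTable(
            tp=pos_p, fn=nrm_p + unc_p + blk_p,
            tn=nrm_a, fp=pos_a + unc_a + blk_a,
            policy=policy,
        )
    return ContingencyTable(tp=pos_p, fn=nrm_p, tn=nrm_a, fp=pos_a, policy=policy)


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def diagnostic_metrics(ct: ContingencyTable) -> Dict[str, Optional[float]]:
    """Sensitivity, specificity, accuracy, PPV and NPV as proportions.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """
    return {
        "sensitivity": _ratio(ct.tp, ct.tp + ct.fn),
        "specificity": _ratio(ct.tn, ct.tn + ct.fp),
        "accuracy": _ratio(ct.tp + ct.tn, ct.total),
        "ppv": _ratio(ct.tp, ct.tp + ct.fp),
        "npv": _ratio(ct.tn, ct.tn + ct.fn),
    }


def undetected_breakdown(xtab: LabelCrossTab) -> Dict[str, Optional[float]]:
    """Decompose the AF cases the device failed to flag as "possible AF".

    Returns the undetected fraction of all ECG-AF cases, and — among the
    undetected — the shares due to "unclassified" output alone and to
    unreadable (unclassified + blank) output.
    """
    nrm_p, pos_p, unc_p, blk_p = xtab.af_present
    n_af = sum(xtab.af_present)
    if n_af == 0:
        raise ValueError("cross-tab has no AF-present cases")
    undetected = nrm_p + unc_p + blk_p
    return {
        "undetected_fraction": undetected / n_af,
        "frac_unclassified_of_undetected": _ratio(unc_p, undetected),
        "frac_unreadable_of_undetected": _ratio(unc_p + blk_p, undetected),
    }


def round_half_up_pct(proportion: float) -> int:
    """Round a proportion to a whole percent, half away from zero (report style)."""
    return int(math.floor(100.0 * proportion + 0.5))


def crosstab_report(xtab: LabelCrossTab) -> "pd.DataFrame":  # noqa: F821
    """Metric rows for both unreadable policies, rounded and unrounded."""
    import pandas as pd

    rows = []
    for policy in UnreadablePolicy:
        ct = build_contingency(xtab, policy)
        m = diagnostic_metrics(ct)
        rows.append(
            {
                "policy": policy.value,
                "n": ct.total,
                "tp": ct.tp, "fp": ct.fp, "tn": ct.tn, "fn": ct.fn,
                **{k: v for k, v in m.items()},
                **{
                    f"{k}_pct": (None if v is None else round_half_up_pct(v))
                    for k, v in m.items()
                },
            }
        )
    return pd.DataFrame(rows)
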