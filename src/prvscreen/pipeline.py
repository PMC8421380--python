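"""End-to-end screening pipeline: cohort -> PRV -> classification -> evaluation.

``run_pipeline`` takes a :class:`RunConfig` (synthetic-cohort settings or
paths to cohort CSVs), computes the six PRV statistics per reading, evaluates
each requested statistic (ROC/AUC with CI, repeated cross-validated AUC,
decision curve, precision-recall curve at the cohort's own and an assumed
prevalence, a threshold table) for the first reading and the mean of two
readings, cross-tabulates the device labels against ECG ground truth under
both unreadable policies, and writes everything to an output directory:

- ``prv.csv`` — per-reading PRV statistics;
- ``roc_<param>.csv``, ``pr_<param>.csv``, ``decision_<param>.csv`` — curves;
- ``thresholds_<param>.csv`` — threshold-specific metrics;
- ``metrics.json`` — AUCs, CV summaries, KMCM metrics, undetected breakdown;
- ``kmcm_report.csv`` — Table-style device metrics under both policies;
- ``run_log.json`` — resolved config, seed, unevaluable recordings,
  calibration diagnostics.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import io as pio
from .cohort import CohortConfig, ParticipantRecord, simulate_cohort
from .evaluate import (
    DEFAULT_PT_GRID,
    CurveSet,
    ScoredCohort,
    decision_curve,
    precision_recall,
    repeated_cv_auc,
    roc_auc,
    threshold_table,
)
from .kmcm import (
    LabelCrossTab,
    UnreadablePolicy,
    build_contingency,
    crosstab_report,
    diagnostic_metrics,
    undetected_breakdown,
)
from .prv import PRV_PARAMETERS, BeatFilterConfig, InsufficientBeatsError, compute_prv

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compute_cohort_prv", "scored_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; JSON/YAML-loadable via ``from_dict``."""

    synthetic: Optional[CohortConfig] = None
    participants_csv: Optional[str] = None
    intervals_csv: Optional[str] = None
    exclusion_fraction: float = 0.25
    ipp_fraction: float = 0.15
    parameters: Tuple[str, ...] = PRV_PARAMETERS
    n_thresholds: int = 25  # quantile grid per parameter
    pt_grid: Tuple[float, ...] = DEFAULT_PT_GRID
    prevalence_adjust: float = 0.10
    cv_folds: int = 10
    cv_reps: int = 10
    run_cv: bool = True
    seed: int = 0
    out_dir: str = "prvscreen_run"

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("parameter list may not be empty")
        unknown = set(self.parameters) - set(PRV_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown PRV parameters {sorted(unknown)}")
        has_files = self.participants_csv is not None and self.intervals_csv is not None
        if (self.synthetic is None) == (not has_files):
            raise ValueError(
                "configure exactly one cohort source: synthetic settings or both CSV paths"
            )
        if self.synthetic is None:
            for p in (self.participants_csv, self.intervals_csv):
                if not Path(p).exists():
                    raise FileNotFoundError(f"cohort file not found: {p}")
        if not (0.0 < self.prevalence_adjust < 1.0):
            raise ValueError("prevalence_adjust must lie in (0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if data.get("synthetic") is not None:
            data["synthetic"] = CohortConfig(**data["synthetic"])
        for key in ("parameters", "pt_grid"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineResult:
    records: List[ParticipantRecord]
    prv_first: Dict[str, "np.ndarray"]  # parameter -> per-participant value (NaN if unevaluable)
    prv_mean: Dict[str, "np.ndarray"]
    metrics: dict
    out_dir: Path


def compute_cohort_prv(
    records: Sequence[ParticipantRecord], filter_config: BeatFilterConfig
) -> Tuple[list, List[dict]]:
    """PRV results for every reading; unevaluable recordings are logged, not fatal."""
    results, failures = [], []
    for rec in records:
        for reading in rec.readings:
            try:
                results.append(compute_prv(reading, filter_config))
            except InsufficientBeatsError as exc:
                failures.append(
                    {
                        "participant_id": rec.participant_id,
                        "reading_index": reading.reading_index,
                        "reason": str(exc),
                    }
                )
    return results, failures


def scored_cohort(
    records: Sequence[ParticipantRecord],
    prv_by_key: Dict[Tuple[str, int], object],
    parameter: str,
    *,
    use_mean_of_two: bool = False,
) -> Tuple[ScoredCohort, List[str]]:
    """Assemble a ScoredCohort for one statistic; returns (cohort, skipped ids).

    ``use_mean_of_two`` averages the first and second readings; participants
    lacking an evaluable required reading are skipped (reported separately).
    """
    scores, labels, skipped = [], [], []
    for rec in records:
        r1 = prv_by_key.get((rec.participant_id, 1))
        if use_mean_of_two:
            r2 = prv_by_key.get((rec.participant_id, 2))
            if r1 is None or r2 is None:
                skipped.append(rec.participant_id)
                continue
            scores.append((r1.value(parameter) + r2.value(parameter)) / 2.0)
        else:
            if r1 is None:
                skipped.append(rec.participant_id)
                continue
            scores.append(r1.value(parameter))
        labels.append(rec.ecg_af)
    return ScoredCohort(np.asarray(scores), np.asarray(labels, dtype=bool)), skipped


def _curve_frame(curve: CurveSet) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame({"x": curve.x, "y": curve.y, "threshold": curve.thresholds})


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        cohort_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        records = simulate_cohort(cohort_cfg)
        pio.write_cohort(records, out / "cohort")
    else:
        records = pio.load_cohort(config.participants_csv, config.intervals_csv)

    filter_cfg = BeatFilterConfig(config.exclusion_fraction, config.ipp_fraction)
    prv_results, prv_failures = compute_cohort_prv(records, filter_cfg)
    pio.write_prv_results(prv_results, out / "prv.csv")
    prv_by_key = {(r.participant_id, r.reading_index): r for r in prv_results}

    have_second = all(len(r.readings) >= 2 for r in records)
    metrics: dict = {"parameters": {}, "n_participants": len(records)}
    calibration_log = {}
    prv_first: Dict[str, np.ndarray] = {}
    prv_mean: Dict[str, np.ndarray] = {}

    rng_seed = np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0] % (2**31)
    for param in config.parameters:
        entry: dict = {}
        cohort1, skipped1 = scored_cohort(records, prv_by_key, param)
        prv_first[param] = cohort1.scores
        roc1 = roc_auc(cohort1)
        entry["auc_first"] = {"auc": roc1.area, "ci": [roc1.ci_low, roc1.ci_high]}
        entry["n_unevaluable_first"] = len(skipped1)
        _curve_frame(roc1).to_csv(out / f"roc_{param}.csv", index=False)

        thr = np.unique(np.quantile(cohort1.scores, np.linspace(0.02, 0.98, config.n_thresholds)))
        threshold_table(cohort1, thr).to_csv(out / f"thresholds_{param}.csv", index=False)

        pr = precision_recall(cohort1)
        pr_adj = precision_recall(cohort1, prevalence=config.prevalence_adjust)
        entry["auprc_first"] = pr.area
        entry["auprc_first_at_adjusted_prevalence"] = pr_adj.area
        _curve_frame(pr).to_csv(out / f"pr_{param}.csv", index=False)

        dc = decision_curve(cohort1, config.pt_grid)
        calibration_log[param] = dc.calibration
        pd.DataFrame(
            {
                "pt": dc.marker.x,
                "net_benefit": dc.marker.y,
                "treat_all": dc.treat_all.y,
                "treat_none": dc.treat_none.y,
            }
        ).to_csv(out / f"decision_{param}.csv", index=False)

        if config.run_cv:
            cv_res = repeated_cv_auc(cohort1, config.cv_folds, config.cv_reps, seed=rng_seed)
            entry["cv_auc"] = {"mean": cv_res.mean_auc, "interval": list(cv_res.interval)}

        if have_second:
            cohort_m, _ = scored_cohort(records, prv_by_key, param, use_mean_of_two=True)
            prv_mean[param] = cohort_m.scores
            roc_m = roc_auc(cohort_m)
            entry["auc_mean_of_two"] = {"auc": roc_m.area, "ci": [roc_m.ci_low, roc_m.ci_high]}
        metrics["parameters"][param] = entry

    xtab = LabelCrossTab.from_records(records)
    kmcm_entry: dict = {"crosstab": {"af_absent": list(xtab.af_absent),
                                     "af_present": list(xtab.af_present)},
                        "n_unreadable": xtab.n_unreadable, "n_readable": xtab.n_readable}
    for policy in UnreadablePolicy:
        ct = build_contingency(xtab, policy)
        kmcm_entry[policy.value] = diagnostic_metrics(ct)
    if sum(xtab.af_present) > 0:
        kmcm_entry["undetected"] = undetected_breakdown(xtab)
    metrics["kmcm"] = kmcm_entry
    crosstab_report(xtab).to_csv(out / "kmcm_report.csv", index=False)

    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2)
    run_log = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "unevaluable_recordings": prv_failures,
        "decision_curve_calibration": calibration_log,
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, default=str)

    return PipelineResult(
        records=records, prv_first=prv_first, prv_mean=prv_mean,
        metrics=metrics, out_dir=out,
    )
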