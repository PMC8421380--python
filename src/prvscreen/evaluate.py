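"""Threshold-free and threshold-specific evaluation of continuous AF markers.

Covers the full screening-evaluation battery for a scored cohort (one PRV
statistic, or a combined score, per participant, against ECG ground truth):

- ROC curve and AUC via the Mann-Whitney identity (ties credited 1/2), with a
  DeLong 95% confidence interval (percentile bootstrap as the alternative);
- per-threshold sensitivity/specificity/PPV/NPV/accuracy/F1 tables;
- prevalence-standardised PPV (Bayes' rule at an assumed prevalence);
- decision curves: net benefit tp/n - (fp/n) * pt/(1-pt) over a grid of
  threshold probabilities, against treat-all and treat-none references, with
  the marker mapped to probabilities by univariate logistic calibration;
- precision-recall curves with trapezoidal area over achieved points;
- repeated stratified k-fold cross-validated AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm, rankdata

from .kmcm import ContingencyTable, diagnostic_metrics

__all__ = [
    "ScoredCohort",
    "CurveSet",
    "DecisionCurveResult",
    "CVResult",
    "roc_auc",
    "auc_mann_whitney",
    "threshold_table",
    "ppv_at_prevalence",
    "net_benefit",
    "decision_curve",
    "precision_recall",
    "repeated_cv_auc",
    "DEFAULT_PT_GRID",
]

DEFAULT_PT_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 4))


class DegenerateCohortError(ValueError):
    """Raised when a curve requires both classes but only one is present."""


@dataclass(frozen=True)
class ScoredCohort:
    """Per-participant marker scores and boolean ECG ground truth."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels, dtype=bool)
        if s.shape != y.shape or s.ndim != 1:
            raise ValueError("scores and labels must be 1-d arrays of equal length")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)

    def __len__(self) -> int:
        return int(self.scores.size)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())

    @property
    def prevalence(self) -> float:
        return self.n_positive / len(self)

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise DegenerateCohortError(
                "curve construction requires at least one positive and one negative label"
            )


@dataclass(frozen=True)
class CurveSet:
    """An ordered evaluation curve: (x, y, threshold) triples plus summaries."""

    kind: str  # roc | decision | precision_recall
    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    area: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @property
    def points(self) -> List[Tuple[float, float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist(), self.thresholds.tolist()))


def auc_mann_whitney(cohort: ScoredCohort) -> float:
    """AUC as P(random positive outscores random negative), ties counted 1/2."""
    cohort.require_both_classes()
    ranks = rankdata(cohort.scores, method="average")
    n_pos, n_neg = cohort.n_positive, cohort.n_negative
    return float(
        (ranks[cohort.labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def _delong_variance(cohort: ScoredCohort) -> float:
    """DeLong variance of the AUC estimate via structural components (midranks)."""
    pos = cohort.scores[cohort.labels]
    neg = cohort.scores[~cohort.labels]
    m, n = pos.size, neg.size
    tz = rankdata(np.concatenate([pos, neg]), method="average")
    tx = rankdata(pos, method="average")
    ty = rankdata(neg, method="average")
    v01 = (tz[:m] - tx) / n  # per-positive placement values
    v10 = 1.0 - (tz[m:] - ty) / m  # per-negative placement values
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(s01 / m + s10 / n)


def _roc_points(cohort: ScoredCohort) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(-cohort.scores, kind="mergesort")
    y = cohort.labels[order]
    s = cohort.scores[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / cohort.n_positive]
    fpr = np.r_[0.0, fps / cohort.n_negative]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def roc_auc(
    cohort: ScoredCohort,
    *,
    ci_method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> CurveSet:
    """ROC curve with AUC and a confidence interval.

    ``ci_method`` is ``"delong"`` (default) or ``"bootstrap"`` (percentile,
    stratified resampling, ``n_boot`` replicates, seeded).
    """
    cohort.require_both_classes()
    auc = auc_mann_whitney(cohort)
    fpr, tpr, thresholds = _roc_points(cohort)
    if ci_method == "delong":
        se = np.sqrt(_delong_variance(cohort))
        z = norm.ppf(1 - alpha / 2)
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = cohort.scores[cohort.labels]
        neg = cohort.scores[~cohort.labels]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, pos.size, replace=True)
            bn = rng.choice(neg, neg.size, replace=True)
            boot = ScoredCohort(
                np.concatenate([bp, bn]),
                np.r_[np.ones(pos.size, bool), np.zeros(neg.size, bool)],
            )
            reps[b] = auc_mann_whitney(boot)
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return CurveSet(
        kind="roc", x=fpr, y=tpr, thresholds=thresholds,
        area=auc, ci_low=float(lo), ci_high=float(hi),
    )


def _f1(sens: Optional[float], ppv: Optional[float]) -> Optional[float]:
    if sens is None or ppv is None or (sens + ppv) == 0:
        return None
    return 2.0 * ppv * sens / (ppv + sens)


def threshold_table(cohort: ScoredCohort, thresholds: Sequence[float]) -> pd.DataFrame:
    """Diagnostic metrics of ``score > t`` for each threshold ``t``.

    Undefined metrics (zero denominators) are reported as NaN.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    rows = []
    y = cohort.labels
    for t in thresholds:
        pred = cohort.scores > t
        ct = ContingencyTable(
            tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
            tn=int((~pred & ~y).sum()), fn=int((~pred & y).sum()),
        )
        m = diagnostic_metrics(ct)
        rows.append({"threshold": float(t), **m, "f1": _f1(m["sensitivity"], m["ppv"])})
    return pd.DataFrame(rows).astype({"threshold": float})


def ppv_at_prevalence(sensitivity: float, specificity: float, prevalence: float) -> Optional[float]:
    """Positive predictive value at an assumed prevalence (Bayes' rule)."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    return num / den if den > 0 else None


def net_benefit(tp: int, fp: int, n: int, pt: float) -> float:
    """Net benefit tp/n - (fp/n) * pt/(1-pt) at threshold probability ``pt``."""
    if not (0.0 < pt < 1.0):
        raise ValueError(f"threshold probability must lie in (0, 1), got {pt}")
    if tp < 0 or fp < 0 or tp + fp > n or n <= 0:
        raise ValueError("counts must satisfy 0 <= tp, fp and tp + fp <= n")
    return tp / n - (fp / n) * pt / (1.0 - pt)


def _logistic_calibrate(cohort: ScoredCohort, ridge: float = 1e-4) -> Tuple[np.ndarray, dict]:
    """Map scores to AF probabilities by univariate logistic calibration.

    A tiny ridge penalty on the slope (after score standardisation) keeps the
    fit well-posed under complete separation, where the unpenalised MLE
    diverges; separable markers then map to probabilities ~0/1.
    """
    y = cohort.labels.astype(float)
    s = cohort.scores
    mu, sigma = s.mean(), s.std()
    z = (s - mu) / sigma if sigma > 0 else np.zeros_like(s)
    prev = np.clip(y.mean(), 1e-12, 1 - 1e-12)

    def objective(params: np.ndarray) -> Tuple[float, np.ndarray]:
        a, b = params
        eta = a + b * z
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        resid = expit(eta) - y
        grad = np.array([resid.mean(), (resid * z).mean() + 2.0 * ridge * b])
        return nll + ridge * b * b, grad

    res = minimize(
        objective, x0=np.array([np.log(prev / (1 - prev)), 0.0]),
        jac=True, method="BFGS", options={"maxiter": 500, "gtol": 1e-9},
    )
    a, b = res.x
    info = {"intercept": float(a), "slope": float(b), "converged": bool(res.success),
            "ridge": ridge}
    return expit(a + b * z), info


@dataclass(frozen=True)
class DecisionCurveResult:
    """Net-benefit curves for a marker and the treat-all/treat-none references."""

    marker: CurveSet
    treat_all: CurveSet
    treat_none: CurveSet
    calibration: Dict[str, float] = field(default_factory=dict)


def decision_curve(
    cohort: ScoredCohort,
    pt_grid: Sequence[float] = DEFAULT_PT_GRID,
    *,
    probabilities: Optional[np.ndarray] = None,
) -> DecisionCurveResult:
    """Decision-curve analysis of a continuous marker.

    The marker is converted to predicted AF probabilities (``probabilities``
    overrides the built-in logistic calibration); at each threshold probability
    pt the prediction "probability >= pt" is scored by net benefit.  Treat-all
    assumes everyone has AF; treat-none is the zero reference.
    """
    cohort.require_both_classes()
    pts = np.asarray(pt_grid, dtype=float)
    if pts.size == 0 or np.any(pts <= 0) or np.any(pts >= 1):
        raise ValueError("pt_grid values must lie strictly inside (0, 1)")
    if probabilities is None:
        probs, cal_info = _logistic_calibrate(cohort)
    else:
        probs = np.asarray(probabilities, dtype=float)
        if probs.shape != cohort.scores.shape:
            raise ValueError("probabilities must align with the cohort")
        cal_info = {"provided": True}

    n = len(cohort)
    y = cohort.labels
    nb_marker = np.empty_like(pts)
    nb_all = np.empty_like(pts)
    for i, pt in enumerate(pts):
        pred = probs >= pt
        nb_marker[i] = net_benefit(int((pred & y).sum()), int((pred & ~y).sum()), n, pt)
        nb_all[i] = net_benefit(int(y.sum()), int((~y).sum()), n, pt)
    zero = np.zeros_like(pts)
    return DecisionCurveResult(
        marker=CurveSet(kind="decision", x=pts, y=nb_marker, thresholds=pts),
        treat_all=CurveSet(kind="decision", x=pts, y=nb_all, thresholds=pts),
        treat_none=CurveSet(kind="decision", x=pts, y=zero, thresholds=pts),
        calibration=cal_info,
    )


def precision_recall(
    cohort: ScoredCohort,
    *,
    prevalence: Optional[float] = None,
) -> CurveSet:
    """Precision-recall curve over the achieved thresholds, with trapezoid area.

    The sweep classifies ``score >= t`` for every distinct score ``t`` in
    descending order.  With ``prevalence`` given, precision is re-standardised
    pointwise to that prevalence via Bayes' rule (sensitivity and specificity
    at each threshold are prevalence-free).  Area is the trapezoid over the
    achieved operating points, anchored at recall 0 with the first point's
    precision.
    """
    cohort.require_both_classes()
    order = np.argsort(-cohort.scores, kind="mergesort")
    y = cohort.labels[order]
    s = cohort.scores[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(y)[distinct].astype(float)
    fp = np.cumsum(~y)[distinct].astype(float)
    n_pos, n_neg = cohort.n_positive, cohort.n_negative

    recall = tp / n_pos
    if prevalence is None:
        precision = tp / (tp + fp)
    else:
        precision = np.array(
            [
                ppv_at_prevalence(tp_i / n_pos, 1.0 - fp_i / n_neg, prevalence)
                for tp_i, fp_i in zip(tp, fp)
            ],
            dtype=float,
        )
    thresholds = s[distinct]

    # anchor at recall 0 with the earliest achieved precision
    r = np.r_[0.0, recall]
    p = np.r_[precision[0], precision]
    area = float(np.sum(np.diff(r) * (p[1:] + p[:-1]) / 2.0))
    return CurveSet(
        kind="precision_recall", x=np.r_[0.0, recall], y=p,
        thresholds=np.r_[np.inf, thresholds], area=area,
    )


@dataclass(frozen=True)
class CVResult:
    """Repeated k-fold cross-validated AUC summary."""

    mean_auc: float
    interval: Tuple[float, float]  # 2.5 / 97.5 percentiles over fold AUCs
    fold_aucs: np.ndarray


def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Index sets for k folds, each containing both classes."""
    pos = rng.permutation(np.nonzero(labels)[0])
    neg = rng.permutation(np.nonzero(~labels)[0])
    folds = [
        np.concatenate([p, q])
        for p, q in zip(np.array_split(pos, k), np.array_split(neg, k))
    ]
    return folds


def repeated_cv_auc(
    cohort: ScoredCohort,
    k: int = 10,
    reps: int = 10,
    seed: Optional[int] = None,
) -> CVResult:
    """AUC on each held-out fold of ``reps`` repetitions of stratified k-fold CV.

    There is no per-fold model fitting — the marker is a fixed univariate
    score — so cross-validation re-estimates the AUC on held-out subsets,
    exposing its sampling variability.  Reported: mean fold AUC and the
    2.5/97.5 percentile interval over all k x reps fold AUCs.
    """
    cohort.require_both_classes()
    if len(cohort) < 2 * k:
        raise ValueError(f"cohort of {len(cohort)} too small for {k}-fold CV")
    if min(cohort.n_positive, cohort.n_negative) < k:
        raise ValueError("each fold needs both classes: minority class smaller than k")
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(reps):
        for idx in _stratified_folds(cohort.labels, k, rng):
            aucs.append(
                auc_mann_whitney(ScoredCohort(cohort.scores[idx], cohort.labels[idx]))
            )
    aucs = np.asarray(aucs)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return CVResult(mean_auc=float(aucs.mean()), interval=(float(lo), float(hi)), fold_aucs=aucs)
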