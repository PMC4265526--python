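"""Percentile threshold predictors of the overlap (target) distance.

A threshold predictor maps each level of the target distance d1 to a
level of a predictor distance d2: given vectors α (percentiles of d1)
and β (one fitted value per α level), a pair is predicted to satisfy
d1 ≤ α_i whenever d2 ≤ β_i. Training picks, for each α_i, the candidate
β (a percentile of d2) maximizing TPR + TNR; per-level ROC curves and
AUC quantify how separable the classes are at that level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import DISTANCE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = 100

#: Headline target-distance reference values at which cross-validated
#: precision is conventionally reported.
REFERENCE_ALPHAS = (0.105, 0.15, 0.205, 0.25)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tp_rate(self) -> float:
        """Sensitivity tp/(tp+fn); NaN when the positive class is empty."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def tn_rate(self) -> float:
        """Specificity tn/(tn+fp); NaN when the negative class is empty."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else math.nan

    @property
    def total_precision(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else math.nan


@dataclass(frozen=True)
class ROCCurve:
    """ROC points for one target level, one point per candidate β."""

    level: float
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), sorted by fpr
    auc: float


@dataclass(frozen=True)
class ThresholdPredictor:
    """The trained mapping m(α_i) = β_i over the percentile levels."""

    target_name: str
    predictor_name: str
    alpha: np.ndarray
    beta: np.ndarray
    auc: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.alpha) == len(self.beta) == len(self.auc)):
            raise ValueError("alpha, beta and auc must have equal length")
        if np.any(np.diff(self.alpha) < 0):
            raise ValueError("alpha must be non-decreasing")

    @property
    def n_levels(self) -> int:
        return len(self.alpha)

    def level_for_alpha(self, value: float) -> int:
        """1-based level whose α is nearest ``value`` (ties: lower level)."""
        return int(np.argmin(np.abs(self.alpha - value))) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level": np.arange(1, self.n_levels + 1),
            "alpha": self.alpha,
            "beta": self.beta,
            "auc": self.auc,
        })


def percentile_vector(values: Sequence[float],
                      m: int = DEFAULT_LEVELS) -> np.ndarray:
    """Nearest-rank percentile vector: component i is the value at rank
    ceil(i·n/m) of the sorted sample (1-based), for i = 1..m."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot take percentiles of an empty sample")
    ranks = np.ceil(np.arange(1, m + 1) * v.size / m).astype(int) - 1
    return v[ranks]


def _distance_array(sample, name: str) -> np.ndarray:
    if name not in DISTANCE_NAMES:
        raise ValueError(f"unknown distance {name!r}")
    raw = [getattr(p, name) for p in sample.pairs]
    missing = [f"({p.id1}, {p.id2})"
               for p, v in zip(sample.pairs, raw) if v is None]
    if missing:
        shown = ", ".join(missing[:5])
        raise ValueError(
            f"distance {name!r} missing for {len(missing)} pair(s): {shown}"
            + ("…" if len(missing) > 5 else ""))
    return np.asarray(raw, dtype=float)


def confusion_at(sample, target: str, predictor: str,
                 alpha: float, beta: float) -> ConfusionCounts:
    """Confusion counts of the rule "predict d1 ≤ α iff d2 ≤ β"."""
    d1 = _distance_array(sample, target)
    d2 = _distance_array(sample, predictor)
    pos = d1 <= alpha
    pred = d2 <= beta
    return ConfusionCounts(tp=int(np.sum(pos & pred)),
                           fp=int(np.sum(~pos & pred)),
                           tn=int(np.sum(~pos & ~pred)),
                           fn=int(np.sum(pos & ~pred)))


def _roc_from_rates(fpr: np.ndarray, tpr: np.ndarray
                    ) -> tuple[tuple[tuple[float, float], ...], float]:
    """Anchor, sort lexicographically by (fpr, tpr), trapezoid-integrate.

    Corner points of the empirical step curve are kept (vertical runs at
    one fpr contribute zero width), so with exhaustive thresholds the
    area equals the Mann-Whitney statistic, tied values receiving the
    standard half credit through the diagonal segments.
    """
    pts = np.column_stack([np.concatenate([[0.0], fpr, [1.0]]),
                           np.concatenate([[0.0], tpr, [1.0]])])
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    points = []
    for x, y in pts:  # drop exact duplicates only
        if not points or points[-1] != (float(x), float(y)):
            points.append((float(x), float(y)))
    if (0.0, 1.0) in points:
        auc = 1.0  # ideal curve: exact area, no float summation error
    else:
        arr = np.array(points)
        auc = float(np.trapezoid(arr[:, 1], arr[:, 0]))
    return tuple(points), auc


def roc_curve(sample, target: str, predictor: str, alpha: float,
              candidate_betas: Sequence[float]) -> ROCCurve:
    """ROC curve of the threshold rule at one target level.

    One (fpr, tpr) point per candidate β, plus the (0,0) and (1,1)
    anchors; AUC is the trapezoidal area. If the sample has an empty
    positive or negative class at this α the AUC is NaN.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    betas = np.asarray(candidate_betas, dtype=float)
    if betas.size == 0:
        raise ValueError("candidate_betas is empty")
    d1 = _distance_array(sample, target)
    d2 = _distance_array(sample, predictor)
    pos = d1 <= alpha
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return ROCCurve(level=alpha, points=((0.0, 0.0), (1.0, 1.0)),
                        auc=math.nan)
    pred = d2[:, None] <= betas[None, :]
    tpr = pred[pos].sum(axis=0) / n_pos
    fpr = pred[~pos].sum(axis=0) / n_neg
    points, auc = _roc_from_rates(fpr, tpr)
    return ROCCurve(level=alpha, points=points, auc=auc)


def train(sample, target: str = "bt", predictor: str = "af",
          m: int = DEFAULT_LEVELS) -> ThresholdPredictor:
    """Fit the β vector (and per-level AUC) on one pair sample.

    α is the percentile vector of the target distance and the candidate
    β values are the percentile vector of the predictor distance. At
    each level the β maximizing TPR + TNR is adopted (ties broken toward
    the smallest β). Levels where one class is empty get β = NaN and
    AUC = NaN; their count is logged.
    """
    d1 = _distance_array(sample, target)
    d2 = _distance_array(sample, predictor)
    if np.all(d1 == d1[0]):
        raise ValueError(
            f"target distance {target!r} is degenerate (all values equal)")
    alpha = percentile_vector(d1, m)
    betas = percentile_vector(d2, m)
    pred = d2[:, None] <= betas[None, :]  # n_pairs × m, reused per level
    beta_out = np.full(m, math.nan)
    auc_out = np.full(m, math.nan)
    n_na = 0
    for i in range(m):
        pos = d1 <= alpha[i]
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            n_na += 1
            continue
        tpr = pred[pos].sum(axis=0) / n_pos
        fpr = pred[~pos].sum(axis=0) / n_neg
        j = int(np.argmax(tpr - fpr))  # betas ascend → first max = smallest β
        beta_out[i] = betas[j]
        _, auc_out[i] = _roc_from_rates(fpr, tpr)
    if n_na:
        logger.info("train(%s by %s): %d of %d levels have an empty class "
                    "and were left undefined", target, predictor, n_na, m)
    return ThresholdPredictor(target_name=target, predictor_name=predictor,
                              alpha=alpha, beta=beta_out, auc=auc_out)


def apply(predictor: ThresholdPredictor, sample,
          level: int) -> tuple[ConfusionCounts, float, float]:
    """Evaluate the trained rule at one 1-based level on a held-out sample.

    Returns the confusion counts plus (tp_rate, tn_rate); a rate is NaN
    when its class is empty at this level.
    """
    if not 1 <= level <= predictor.n_levels:
        raise ValueError(f"level {level} outside 1..{predictor.n_levels}")
    a = predictor.alpha[level - 1]
    b = predictor.beta[level - 1]
    if math.isnan(b):
        raise ValueError(f"level {level} was undefined at training time")
    counts = confusion_at(sample, predictor.target_name,
                          predictor.predictor_name, a, b)
    return counts, counts.tp_rate, counts.tn_rate


@dataclass(frozen=True)
class CrossValResult:
    """Per-fold, per-level cross-validation rates.

    ``records`` is a long DataFrame (fold, level, alpha, beta, counts,
    rates); ``table`` is the wide per-fold layout with TP%/TN% columns
    per requested level and an ``Average`` row across folds.
    """

    records: pd.DataFrame
    table: pd.DataFrame


def cross_validate(samples: Sequence, target: str = "bt",
                   predictor: str = "af",
                   reference_alphas: Sequence[float] = REFERENCE_ALPHAS,
                   m: int = DEFAULT_LEVELS) -> CrossValResult:
    """Leave-one-in cross-validation over pair samples.

    For each fold the predictor is trained on one sample and evaluated
    on all the others, whose confusion counts are pooled per level.
    Rates are reported at the levels whose trained α is nearest each
    requested reference value; the ``Average`` row is the mean across
    folds, with NaN levels excluded.
    """
    if len(samples) < 2:
        raise ValueError("cross-validation needs at least 2 samples")
    rows = []
    for train_sample in samples:
        tp = train(train_sample, target, predictor, m)
        for ref in reference_alphas:
            level = tp.level_for_alpha(ref)
            a, b = tp.alpha[level - 1], tp.beta[level - 1]
            pooled = ConfusionCounts(0, 0, 0, 0)
            for test_sample in samples:
                if test_sample is train_sample:
                    continue
                if math.isnan(b):
                    continue
                c = confusion_at(test_sample, target, predictor, a, b)
                pooled = ConfusionCounts(tp=pooled.tp + c.tp,
                                         fp=pooled.fp + c.fp,
                                         tn=pooled.tn + c.tn,
                                         fn=pooled.fn + c.fn)
            rows.append({
                "fold": train_sample.label,
                "reference": ref,
                "level": level,
                "alpha": a,
                "beta": b,
                "tp": pooled.tp, "fp": pooled.fp,
                "tn": pooled.tn, "fn": pooled.fn,
                "tp_rate": pooled.tp_rate,
                "tn_rate": pooled.tn_rate,
                "total_precision": pooled.total_precision,
            })
    records = pd.DataFrame(rows)
    wide = records.pivot(index="fold", columns="reference",
                         values=["tp_rate", "tn_rate"])
    wide = (wide * 100.0).round(2)
    wide.columns = [f"{'TP' if v == 'tp_rate' else 'TN'}%@{ref}"
                    for v, ref in wide.columns]
    wide = wide[sorted(wide.columns,
                       key=lambda c: (float(c.split("@")[1]), c[:2]))]
    wide.loc["Average"] = wide.mean(axis=0, skipna=True).round(2)
    return CrossValResult(records=records, table=wide)


def pearson_matrix(sample) -> pd.DataFrame:
    """Pearson correlation matrix of the four distances over a sample."""
    data = {}
    for name in DISTANCE_NAMES:
        col = _distance_array(sample, name)
        if np.all(col == col[0]):
            raise ValueError(f"distance {name!r} has zero variance")
        data[name] = col
    mat = np.corrcoef(np.column_stack(list(data.values())), rowvar=False)
    return pd.DataFrame(mat, index=list(data), columns=list(data))
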