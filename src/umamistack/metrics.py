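"""Binary-classification metrics and the repeated stratified CV protocol.

Metrics are computed from the four confusion counts:

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    Sn   = TP / (TP + FN)
    Sp   = TN / (TN + FP)
    BACC = (Sn + Sp) / 2
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate denominators (a metric's denominator equal to zero) yield 0
rather than NaN so reports are total. AUC is the area under the ROC
curve with tie-averaged ranks (pairwise-concordance equivalent),
delegated to scikit-learn.

The evaluation protocol is repeated stratified k-fold cross-validation:
within each repetition the out-of-fold predictions of the k folds are
pooled into a single confusion table (micro averaging), and the
per-repetition reports are averaged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .baselines import derive_seed
from .io import LabeledDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with class 1 as positive."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    for name, arr in (("y_true", yt), ("y_pred", yp)):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary values")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def counts_from_rates(sn: float, sp: float, n_pos: int, n_neg: int) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed Sn/Sp and class
    sizes (rounding to the nearest integer count)."""
    tp = round(sn * n_pos)
    tn = round(sp * n_neg)
    return ConfusionCounts(tp=tp, tn=tn, fp=n_neg - tn, fn=n_pos - tp)


@dataclass
class MetricsReport:
    acc: float
    bacc: float
    sn: float
    sp: float
    mcc: float
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("%s has zero denominator; reporting 0", what)
        return 0.0
    return num / den


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator is 0."""
    den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / den


def compute_metrics(
    c: ConfusionCounts,
    scores: Sequence[float] | None = None,
    y_true: Sequence[int] | None = None,
) -> MetricsReport:
    """Full metrics report from counts, plus AUC when scores are given."""
    acc = _safe_div(c.tp + c.tn, c.total, "ACC")
    sn = _safe_div(c.tp, c.tp + c.fn, "Sn")
    sp = _safe_div(c.tn, c.tn + c.fp, "Sp")
    bacc = (sn + sp) * 0.5
    mcc = mcc_from_counts(c)
    auc = float("nan")
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true is required to compute AUC from scores")
        yt = np.asarray(y_true)
        if yt.shape[0] != len(scores):
            raise ValueError("scores must be parallel to y_true")
        if len(np.unique(yt)) == 2:
            auc = float(roc_auc_score(yt, np.asarray(scores, dtype=float)))
        else:
            logger.debug("AUC undefined for single-class y_true; reporting 0")
            auc = 0.0
    return MetricsReport(acc=acc, bacc=bacc, sn=sn, sp=sp, mcc=mcc, auc=auc)


def metrics_from_predictions(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Report from scores using the strict greater-than threshold rule."""
    yp = (np.asarray(scores, dtype=float) > threshold).astype(np.int64)
    return compute_metrics(confusion(y_true, yp), scores=scores, y_true=y_true)


@dataclass(frozen=True)
class CVProtocol:
    """Repeated stratified k-fold cross-validation settings."""

    k: int = 10
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class CVResult:
    mean: MetricsReport
    per_repetition: list[MetricsReport]


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    vals = {
        f.name: float(np.mean([getattr(r, f.name) for r in reports]))
        for f in fields(MetricsReport)
    }
    return MetricsReport(**vals)


ScoreFn = Callable[[LabeledDataset, LabeledDataset, int], np.ndarray]


def repeated_stratified_cv(
    ds: LabeledDataset,
    fit_score: ScoreFn,
    protocol: CVProtocol | None = None,
) -> CVResult:
    """Evaluate a trainer by repeated stratified k-fold cross-validation.

    ``fit_score(train_ds, test_ds, seed)`` must train on ``train_ds``
    only and return P(umami) scores for ``test_ds``. Per repetition the
    out-of-fold scores are pooled into one report; the mean report
    averages the repetitions.
    """
    protocol = protocol or CVProtocol()
    y = ds.labels
    if np.bincount(y, minlength=2).min() < protocol.k:
        raise ValueError(f"each class needs >= k={protocol.k} members")
    reports = []
    for rep in range(protocol.repetitions):
        rep_seed = derive_seed(protocol.seed, "cv-rep", rep)
        skf = StratifiedKFold(
            n_splits=protocol.k, shuffle=True, random_state=rep_seed
        )
        scores = np.empty(len(ds))
        for f, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(len(ds)), y)
        ):
            fold_seed = derive_seed(rep_seed, "fold", f)
            scores[test_idx] = fit_score(
                ds.subset(train_idx), ds.subset(test_idx), fold_seed
            )
        reports.append(metrics_from_predictions(y, scores))
    return CVResult(mean=_mean_report(reports), per_repetition=reports)
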