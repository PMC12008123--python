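"""Confusion-matrix metrics, threshold-free curves, repeated evaluation.

Class 1 (super-enhancer) is the positive class throughout.  The headline
metrics are

    ACC = (TP + TN) / (TP + TN + FP + FN)
    Pre = TP / (TP + FP)        Rec = TP / (TP + FN)
    F1  = 2 TP / (2 TP + FP + FN)

plus AUROC (trapezoidal, equivalently the tie-averaged rank statistic) and
AUPR (step interpolation, i.e. average precision).  Undefined precision or
recall denominators yield a flagged 0 with a warning rather than NaN so
repeated-run aggregation stays total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)


class MetricsError(ValueError):
    """Invalid metric inputs (empty, non-binary, single-class...)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.size == 0:
        raise MetricsError(f"{name} is empty")
    vals = set(np.unique(arr).tolist())
    if not vals <= {0, 1}:
        raise MetricsError(f"{name} must be binary 0/1, got values {sorted(vals)}")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """2x2 confusion counts with class 1 positive."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if len(y_true) != len(y_pred):
        raise MetricsError("y_true and y_pred have different lengths")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(acc, precision, recall, f1) from confusion counts.

    TP+FP = 0 or TP+FN = 0 make precision/recall undefined; both are
    reported as 0 with a warning.
    """
    if counts.total == 0:
        raise MetricsError("cannot compute metrics on zero samples")
    acc = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        logger.warning("precision undefined (no predicted positives); reporting 0")
        precision = 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        logger.warning("recall undefined (no true positives present); reporting 0")
        recall = 0.0
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = 2 * counts.tp / denom if denom > 0 else 0.0
    return acc, precision, recall, f1


def roc_pr_curves(y_true, y_score) -> tuple[float, float]:
    """(AUROC, AUPR) of real-valued scores against binary truth.

    AUROC is the trapezoidal area over all thresholds (identical to the
    Mann-Whitney rank statistic with ties averaged); AUPR uses the standard
    step interpolation of the precision-recall curve.
    """
    y_true = _check_binary(y_true, "y_true")
    y_score = np.asarray(y_score, dtype=float)
    if len(y_true) != len(y_score):
        raise MetricsError("y_true and y_score have different lengths")
    if len(set(y_true.tolist())) < 2:
        raise MetricsError("both classes must be present to compute curves")
    return float(roc_auc_score(y_true, y_score)), float(average_precision_score(y_true, y_score))


@dataclass
class MetricsReport:
    """Headline metrics, optionally aggregated over repeated runs."""

    acc: float
    precision: float
    recall: float
    f1: float
    auroc: float
    aupr: float
    counts: ConfusionCounts | None = None
    n_runs: int = 1
    per_run: list[dict[str, float]] = field(default_factory=list)
    std: dict[str, float] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auroc": self.auroc,
            "aupr": self.aupr,
        }


def evaluate_scores(y_true, y_score, threshold: float = 0.5) -> MetricsReport:
    """Full report from probabilities: label 1 iff score >= threshold."""
    y_true = _check_binary(y_true, "y_true")
    y_score = np.asarray(y_score, dtype=float)
    y_pred = (y_score >= threshold).astype(int)
    counts = confusion(y_true, y_pred)
    acc, pre, rec, f1 = compute_metrics(counts)
    auroc, aupr = roc_pr_curves(y_true, y_score)
    report = MetricsReport(acc, pre, rec, f1, auroc, aupr, counts=counts)
    report.per_run = [report.as_dict()]
    return report


def repeated_evaluation(run, n_repeats: int, base_seed: int) -> MetricsReport:
    """Aggregate a seeded evaluation over repeated runs.

    ``run(seed)`` must return ``(y_true, y_score)`` for one full
    re-split/re-train/re-score cycle; runs use seeds base_seed + r.  The
    report carries per-run metrics, their means (headline fields) and
    standard deviations; failed runs are logged and excluded.
    """
    if n_repeats < 1:
        raise MetricsError(f"n_repeats must be >= 1, got {n_repeats}")
    per_run: list[dict[str, float]] = []
    failures: list[str] = []
    for r in range(n_repeats):
        seed = base_seed + r
        try:
            y_true, y_score = run(seed)
            per_run.append(evaluate_scores(y_true, y_score).as_dict())
        except Exception as exc:
            logger.error("repeat %d (seed %d) failed: %s", r, seed, exc)
            failures.append(f"seed {seed}: {exc}")
    if not per_run:
        raise RuntimeError(f"all {n_repeats} repeats failed: {failures}")
    keys = per_run[0].keys()
    means = {k: float(np.mean([m[k] for m in per_run])) for k in keys}
    stds = {k: float(np.std([m[k] for m in per_run])) for k in keys}
    return MetricsReport(
        acc=means["acc"],
        precision=means["precision"],
        recall=means["recall"],
        f1=means["f1"],
        auroc=means["auroc"],
        aupr=means["aupr"],
        n_runs=len(per_run),
        per_run=per_run,
        std=stds,
        failures=failures,
    )
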