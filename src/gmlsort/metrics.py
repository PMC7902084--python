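"""Evaluation of a ranked single-particle selection.

A ranking of m test snapshots is swept over cutoffs tau = 1..m; at
each tau the leading tau snapshots are called singles.  From the
cumulative true/false positive counts the module derives

    FPR(tau) = FP/N,  TPR(tau) = TP/P  (= recall),
    precision(tau) = TP/(TP + FP),
    purity  chi(tau) = (TP - FP)/P,

and two operating points: the maximum-purity cutoff, and the "best
prediction" at the ROC point furthest from the diagonal (argmax of
TPR - FPR, the Youden statistic).  chi is floored at zero where false
positives outnumber true positives, the regime where the contamination
factor 1 - FP/TP loses meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "EvalReport",
    "OperatingPoint",
    "sweep_counts",
    "precision_at",
    "recall_at",
    "purity_at",
    "evaluate",
    "roc_curve",
    "best_prediction_point",
    "max_purity_point",
]


def sweep_counts(ranking: np.ndarray, labels: np.ndarray):
    """Cumulative TP(tau), FP(tau) along a ranking, tau = 1..m."""
    ranking = np.asarray(ranking)
    labels = np.asarray(labels)
    if len(ranking) != len(labels):
        raise DataError("ranking and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise DataError("labels must be binary (0/1)")
    ordered = labels[ranking].astype(np.int64)
    tp = np.cumsum(ordered)
    fp = np.cumsum(1 - ordered)
    return tp, fp


def precision_at(tp, fp):
    """TP / (TP + FP); undefined (nan) where no snapshot is selected."""
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    total = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, tp / np.where(total > 0, total, 1.0), np.nan)
    return out if out.ndim else float(out)


def recall_at(tp, P: int):
    """TP / P, the true positive rate."""
    if P <= 0:
        raise DataError("P (number of positives) must be > 0")
    out = np.asarray(tp, dtype=float) / P
    return out if out.ndim else float(out)


def purity_at(tp, fp, P: int):
    """chi = (TP - FP)/P, floored at 0 when false positives dominate."""
    if P <= 0:
        raise DataError("P (number of positives) must be > 0")
    out = np.clip((np.asarray(tp, dtype=float) - np.asarray(fp, dtype=float)) / P, 0.0, None)
    return out if out.ndim else float(out)


@dataclass
class OperatingPoint:
    """One chosen cutoff with its quality figures."""

    tau: int
    precision: float
    recall: float
    chi: float
    fpr: float
    tpr: float


@dataclass
class EvalReport:
    """Full tau-sweep curves for one prediction against ground truth."""

    tau: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    P: int
    N: int
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    chi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.tau,
                "TP": self.tp,
                "FP": self.fp,
                "TPR": self.tpr,
                "FPR": self.fpr,
                "precision": self.precision,
                "chi": self.chi,
            }
        )


def evaluate(ranking: np.ndarray, labels: np.ndarray) -> EvalReport:
    """Sweep all cutoffs of a ranking and assemble the evaluation curves."""
    labels = np.asarray(labels)
    tp, fp = sweep_counts(ranking, labels)
    P = int(labels.sum())
    N = int(len(labels) - P)
    if P == 0:
        raise DataError("no positives in the ground truth")
    if N == 0:
        raise DataError("no negatives in the ground truth")
    m = len(labels)
    return EvalReport(
        tau=np.arange(1, m + 1),
        tp=tp,
        fp=fp,
        P=P,
        N=N,
        tpr=tp / P,
        fpr=fp / N,
        precision=precision_at(tp, fp),
        chi=purity_at(tp, fp, P),
    )


def roc_curve(report: EvalReport):
    """(FPR(tau), TPR(tau)) arrays, a monotone curve ending at (1, 1)."""
    return report.fpr, report.tpr


def best_prediction_point(report: EvalReport) -> OperatingPoint:
    """ROC point furthest from the diagonal: argmax TPR - FPR (smallest tau on ties).

    The maximal perpendicular distance to the diagonal is a monotone
    function of TPR - FPR, so the Youden form is used for determinism.
    """
    i = int(np.argmax(report.tpr - report.fpr))
    return _point(report, i)


def max_purity_point(report: EvalReport) -> OperatingPoint:
    """Cutoff maximizing the purity chi (smallest tau on ties)."""
    i = int(np.argmax(report.chi))
    return _point(report, i)


def _point(report: EvalReport, i: int) -> OperatingPoint:
    return OperatingPoint(
        tau=int(report.tau[i]),
        precision=float(report.precision[i]),
        recall=float(report.tpr[i]),
        chi=float(report.chi[i]),
        fpr=float(report.fpr[i]),
        tpr=float(report.tpr[i]),
    )
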