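"""Classification metrics and the motif-significance convention.

Six metrics summarize TFBS prediction: precision, recall, F1, accuracy,
area under the ROC curve (trapezoid over all thresholds, equivalently the
tie-corrected pairwise-ordering probability) and the area under the
precision-recall curve in the average-precision convention.  Confusion
counts use a 0.5 probability threshold.

Motif significance follows the convention that an externally supplied
match p-value below 0.05 — i.e. -log10(p) strictly above
-log10(0.05) = 1.301 — marks a significant motif.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricReport",
    "compute_metrics",
    "significance_threshold",
    "is_significant",
    "write_metrics_tsv",
]


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    acc: float
    auc: float  # NaN when only one class is present
    prc: float  # NaN when only one class is present
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN) at threshold 0.5
    n_eval: int

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "acc": self.acc, "auc": self.auc, "prc": self.prc,
        }


def compute_metrics(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> MetricReport:
    """Compute the six evaluation metrics from labels and predicted probabilities.

    Ratio metrics with an empty denominator are reported as 0.0; AUC and
    PRC are NaN (undefined) when only one class is present.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"labels and probabilities differ in length: {y.shape} vs {p.shape}")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    n = y.size
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    acc = (tp + tn) / n if n else 0.0
    if len(np.unique(y)) < 2:
        auc = prc = float("nan")
    else:
        auc = float(roc_auc_score(y, p))
        prc = float(average_precision_score(y, p))
    return MetricReport(precision, recall, f1, acc, auc, prc, (tp, fp, fn, tn), n)


def significance_threshold() -> float:
    """The -log10(p) cut-off corresponding to p = 0.05 (≈ 1.301)."""
    return -math.log10(0.05)


def is_significant(neg_log10_p: float) -> bool:
    """Strictly above the threshold ⇒ significant; p = 0.05 exactly is not."""
    return neg_log10_p > significance_threshold()


def write_metrics_tsv(report: MetricReport, path: str | Path) -> None:
    tp, fp, fn, tn = report.confusion
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in report.as_dict().items():
            fh.write(f"{k}\t{v:.6f}\n")
        fh.write(f"tp\t{tp}\nfp\t{fp}\nfn\t{fn}\ntn\t{tn}\nn_eval\t{report.n_eval}\n")
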