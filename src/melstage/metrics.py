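"""Scoring-agreement metrics: confusion matrix, accuracy, precision,
recall, F1, Cohen's kappa and the Test Cost Index (TCI).

Per-class figures use one-vs-rest TP/FP/FN/TN counts.  Cohen's kappa is
``(p0 - pe) / (1 - pe)`` with observed agreement ``p0`` and chance
agreement ``pe`` from the product of the marginals.  The TCI is the
mean *cubed signed* difference between the integer class codes of the
true and predicted stages — it is sign-sensitive (systematically
over-staging and under-staging cancel) and depends on the fixed code
order ``W=0, S1=1, S2=2, S3=3, REM=4``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from melstage.staging import STAGES, STAGE_TO_CODE


class DegenerateKappaError(ZeroDivisionError):
    """Chance agreement is exactly 1; kappa is undefined."""


def _codes(labels: Sequence) -> np.ndarray:
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            if lab not in STAGE_TO_CODE:
                raise ValueError(f"unknown stage label {lab!r}")
            out[i] = STAGE_TO_CODE[lab]
        else:
            code = int(lab)
            if not 0 <= code < len(STAGES):
                raise ValueError(f"stage code {code} outside 0..{len(STAGES) - 1}")
            out[i] = code
    return out


@dataclass
class ConfusionMatrix:
    """5x5 count matrix; rows are true stages, columns predicted."""

    counts: np.ndarray
    classes: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("confusion matrix entries must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        lines = ["true\\pred," + ",".join(self.classes)]
        for lab, row in zip(self.classes, self.counts):
            lines.append(lab + "," + ",".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def confusion(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionMatrix:
    """Count matrix: cell (i, j) = epochs truly in stage i predicted as j."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label lists differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    t = _codes(true_labels)
    p = _codes(predicted_labels)
    k = len(STAGES)
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return ConfusionMatrix(counts=cm)


def basic_metrics(cm: ConfusionMatrix) -> dict:
    """Overall accuracy and one-vs-rest precision/recall/F1 per class (in %).

    A class with no predicted (resp. true) instances gets precision
    (resp. recall) 0 with a warning; macro averages run over classes
    with nonzero true support so that absent stages do not zero them
    out.
    """
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c).astype(float)
    row = c.sum(axis=1).astype(float)  # true counts
    col = c.sum(axis=0).astype(float)  # predicted counts
    fp = col - tp
    fn = row - tp
    if np.any((tp + fp) == 0) or np.any((tp + fn) == 0):
        warnings.warn("class with no predicted or no true instances; its metric is set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1e-300), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2.0 * precision * recall / np.maximum(precision + recall, 1e-300),
            0.0,
        )
    support = row > 0
    if not support.any():
        raise ValueError("confusion matrix has no true instances")
    return {
        "accuracy": 100.0 * tp.sum() / total,
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "f1": 100.0 * f1,
        "macro_precision": 100.0 * precision[support].mean(),
        "macro_recall": 100.0 * recall[support].mean(),
        "macro_f1": 100.0 * f1[support].mean(),
        "support": row.astype(int),
    }


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement ``(p0 - pe) / (1 - pe)``."""
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p0 = np.trace(c) / total
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if abs(1.0 - pe) < 1e-12:
        raise DegenerateKappaError("chance agreement pe = 1; kappa undefined")
    return float((p0 - pe) / (1.0 - pe))


def test_cost_index(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Mean cubed signed difference of integer stage codes.

    Zero for perfect prediction; positive when predictions sit below
    the true codes on average (under-staging), negative otherwise.
    Swapping the arguments negates it.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label lists differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    t = _codes(true_labels).astype(float)
    p = _codes(predicted_labels).astype(float)
    return float(np.mean((t - p) ** 3))


@dataclass
class EvalReport:
    """Summary of one evaluation run, mirroring the usual reporting table."""

    confusion: ConfusionMatrix
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    kappa: float
    tci: float
    n_epochs: int

    def to_dict(self) -> dict:
        return {
            "n_epochs": self.n_epochs,
            "accuracy_pct": self.accuracy,
            "kappa": self.kappa,
            "tci": self.tci,
            "f1_pct": self.f1,
            "precision_pct": self.precision,
            "recall_pct": self.recall,
            "macro_f1_pct": self.macro_f1,
            "macro_precision_pct": self.macro_precision,
            "macro_recall_pct": self.macro_recall,
            "confusion": self.confusion.counts.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_csv(self, path: str | Path) -> None:
        """One-row table: per-stage F1, ACC, kappa, TCI."""
        header = ["n_epochs"] + [f"F1_{s}" for s in STAGES] + ["ACC", "kappa", "TCI"]
        row = (
            [str(self.n_epochs)]
            + [f"{self.f1[s]:.2f}" for s in STAGES]
            + [f"{self.accuracy:.2f}", f"{self.kappa:.4f}", f"{self.tci:.4f}"]
        )
        Path(path).write_text(",".join(header) + "\n" + ",".join(row) + "\n")


def evaluate(true_labels: Sequence, predicted_labels: Sequence) -> EvalReport:
    """Compute the full report from aligned true/predicted stage lists."""
    cm = confusion(true_labels, predicted_labels)
    bm = basic_metrics(cm)
    return EvalReport(
        confusion=cm,
        accuracy=float(bm["accuracy"]),
        precision={s: float(v) for s, v in zip(STAGES, bm["precision"])},
        recall={s: float(v) for s, v in zip(STAGES, bm["recall"])},
        f1={s: float(v) for s, v in zip(STAGES, bm["f1"])},
        macro_precision=float(bm["macro_precision"]),
        macro_recall=float(bm["macro_recall"]),
        macro_f1=float(bm["macro_f1"]),
        kappa=cohen_kappa(cm),
        tci=test_cost_index(true_labels, predicted_labels),
        n_epochs=cm.total,
    )
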