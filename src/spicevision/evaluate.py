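"""Confusion-matrix construction and the four-metric evaluation suite.

For a K-class single-label problem each class c is scored one-vs-rest from
the confusion matrix (rows = true class, columns = predicted class):

    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100
    precision   = TP / (TP + FP) * 100
    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100

Macro aggregates are unweighted class means; micro precision/sensitivity
pool the counts first, which for single-label data collapses to the overall
correct-classification rate (trace / total).  A useful closed form: the
macro per-class accuracy equals (K*N - 2E) / (K*N) * 100 where E is the
number of misclassified samples, independent of where the errors sit.

Degenerate 0/0 ratios (a class absent and never predicted) are defined as
100 so that a perfect confusion matrix scores 100 on every metric.

Percentages are rendered both rounded (half-up) and truncated, since both
conventions occur in practice when reporting e.g. 88/90 = 97.777...%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    counts: np.ndarray = field(repr=False)
    class_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.class_labels:
            self.class_labels = [str(i + 1) for i in range(self.counts.shape[0])]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_errors(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))


@dataclass
class ClassCounts:
    """One-vs-rest counts for a single class."""

    N_TP: int
    N_FP: int
    N_TN: int
    N_FN: int


def confusion(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    """counts[i][j] = number of samples with true class i+1 predicted j+1."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size == 0:
        raise ValueError("empty label lists")
    if t.shape != p.shape:
        raise ValueError("label lists must have equal length")
    if t.min() < 1 or t.max() > n_classes or p.min() < 1 or p.max() > n_classes:
        raise ValueError("labels must lie in 1..K")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t - 1, p - 1), 1)
    return ConfusionMatrix(counts=counts)


def class_counts(m: ConfusionMatrix, c: int) -> ClassCounts:
    """One-vs-rest TP/FP/TN/FN for 1-based class index c."""
    if not 1 <= c <= m.n_classes:
        raise ValueError(f"class index {c} out of range 1..{m.n_classes}")
    i = c - 1
    tp = int(m.counts[i, i])
    fn = int(m.counts[i].sum() - tp)
    fp = int(m.counts[:, i].sum() - tp)
    tn = int(m.counts.sum() - tp - fn - fp)
    return ClassCounts(N_TP=tp, N_FP=fp, N_TN=tn, N_FN=fn)


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den else 100.0


@dataclass
class MetricsReport:
    per_class: pd.DataFrame = field(repr=False)
    macro: dict[str, float] = field(default_factory=dict)
    micro_precision: float = np.nan
    micro_sensitivity: float = np.nan
    overall_ccr: float = np.nan
    n_errors: int = 0
    total: int = 0


def metrics(m: ConfusionMatrix) -> MetricsReport:
    """Per-class, macro and micro metrics plus the overall CCR (all in %)."""
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    pooled_tp = pooled_fp = pooled_fn = 0
    for c in range(1, m.n_classes + 1):
        cc = class_counts(m, c)
        rows.append({
            "class": m.class_labels[c - 1],
            "accuracy": _ratio(cc.N_TP + cc.N_TN,
                               cc.N_TP + cc.N_TN + cc.N_FP + cc.N_FN),
            "precision": _ratio(cc.N_TP, cc.N_TP + cc.N_FP),
            "sensitivity": _ratio(cc.N_TP, cc.N_TP + cc.N_FN),
            "specificity": _ratio(cc.N_TN, cc.N_TN + cc.N_FP),
        })
        pooled_tp += cc.N_TP
        pooled_fp += cc.N_FP
        pooled_fn += cc.N_FN
    per_class = pd.DataFrame(rows)
    macro = {k: float(per_class[k].mean())
             for k in ("accuracy", "precision", "sensitivity", "specificity")}
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        micro_precision=_ratio(pooled_tp, pooled_tp + pooled_fp),
        micro_sensitivity=_ratio(pooled_tp, pooled_tp + pooled_fn),
        overall_ccr=100.0 * np.trace(m.counts) / m.total,
        n_errors=m.n_errors,
        total=m.total,
    )


def overall_correlation(targets: np.ndarray, outputs: np.ndarray) -> float:
    """Pearson correlation between flattened target and output matrices."""
    t = np.asarray(targets, dtype=float).ravel()
    o = np.asarray(outputs, dtype=float).ravel()
    if t.shape != o.shape:
        raise ValueError("targets and outputs must have equal shapes")
    if t.std() == 0 or o.std() == 0:
        return 0.0
    return float(np.corrcoef(t, o)[0, 1])


def format_pct(value: float, decimals: int = 2, mode: str = "round") -> float:
    """Render a percentage with round-half-up or truncation semantics."""
    scale = 10 ** decimals
    if mode == "round":
        return math.floor(value * scale + 0.5) / scale
    if mode == "truncate":
        return math.floor(value * scale) / scale
    raise ValueError(f"unknown mode {mode!r}")


def report(reports: dict[tuple[str, str], MetricsReport],
           path: str | Path | None = None) -> pd.DataFrame:
    """Summary table of macro metrics per (material, method).

    Columns follow the conventional layout: Accuracy is the macro mean of
    per-class one-vs-rest accuracy; Precision/Sensitivity/Specificity are
    macro means of the corresponding per-class metrics.  The overall CCR is
    carried alongside since plain-text accuracy claims usually mean
    trace/total.
    """
    if not reports:
        raise ValueError("need at least one MetricsReport")
    rows = []
    for (material, method), rep in reports.items():
        rows.append({
            "material": material,
            "method": method,
            "accuracy": format_pct(rep.macro["accuracy"]),
            "precision": format_pct(rep.macro["precision"]),
            "sensitivity": format_pct(rep.macro["sensitivity"]),
            "specificity": format_pct(rep.macro["specificity"]),
            "overall_ccr": format_pct(rep.overall_ccr),
        })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
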