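"""Classification metrics, ROC/AUC and the substructure enrichment factor.

The enrichment factor quantifies a substructure's association with the PBT
class: EF = (a/c) / (b/d) where a = PBT molecules containing the
substructure, b = total PBT molecules, c = total molecules containing the
substructure, d = total molecules.  EF = 1 under statistical independence;
EF > 1 marks over-representation among PBT compounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class ContingencyTable:
    """Counts feeding the classification metrics (tp/tn/fp/fn mode) or the
    enrichment factor (a/b/c/d mode)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EnrichmentTable:
    """a = substructure-bearing PBT molecules, b = total PBT,
    c = substructure-bearing molecules, d = total molecules."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a > min(self.b, self.c) or self.b > self.d or self.c > self.d:
            raise ValueError("inconsistent enrichment counts")


@dataclass
class MetricsReport:
    accuracy: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    fpr: Optional[float]
    confusion: ContingencyTable
    undefined: tuple[str, ...] = ()
    auc: Optional[float] = None
    threshold: Optional[float] = None


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ContingencyTable:
    """Exact TP/TN/FP/FN counts from binary labels and binary predictions."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("length mismatch")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ContingencyTable(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(table: ContingencyTable) -> MetricsReport:
    """Recall TP/(TP+FN), FPR FP/(FP+TN), accuracy (TP+TN)/n and
    specificity TN/(TN+FP); zero-denominator ratios are flagged as
    undefined (None), never silently 0."""
    if table.n == 0:
        raise ValueError("empty contingency table")
    recall = _ratio(table.tp, table.tp + table.fn)
    fpr = _ratio(table.fp, table.fp + table.tn)
    specificity = _ratio(table.tn, table.tn + table.fp)
    accuracy = (table.tp + table.tn) / table.n
    undefined = tuple(
        name
        for name, value in (("recall", recall), ("fpr", fpr), ("specificity", specificity))
        if value is None
    )
    return MetricsReport(
        accuracy=accuracy, recall=recall, specificity=specificity,
        fpr=fpr, confusion=table, undefined=undefined,
    )


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (rank/Mann-Whitney tie handling)."""
    yt = np.asarray(y_true)
    if len(np.unique(yt)) < 2:
        raise ValueError("ROC AUC requires both classes in y_true")
    return float(roc_auc_score(yt, np.asarray(scores, dtype=float)))


def enrichment_factor(table: EnrichmentTable) -> float:
    """EF = (a/c) / (b/d); raises for undefined configurations (no
    substructure-bearing molecules, or no PBT molecules)."""
    if table.c == 0:
        raise ValueError("EF undefined: substructure matches no molecule (c = 0)")
    if table.b == 0:
        raise ValueError("EF undefined: no PBT molecules (b = 0)")
    if table.d == 0:
        raise ValueError("EF undefined: empty dataset (d = 0)")
    return (table.a / table.c) / (table.b / table.d)
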