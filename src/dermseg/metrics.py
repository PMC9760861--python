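"""Segmentation evaluation: binary overlap metrics, multi-class
confusion matrices, and benchmark table emission.

Conventions: TPR = tp/(tp+fn), FPR = fp/(fp+tn) (full-frame denominator),
FNR = fn/(tp+fn), Jaccard = tp/(tp+fp+fn), Dice = 2tp/(2tp+fp+fn).  Any
ratio with a zero denominator is reported as undefined (``None``), never
silently as 0, so that it cannot corrupt medians; table writers render it
as "NA".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class EvalMetrics:
    """Pixel confusion counts of one predicted/true mask pair plus the
    derived overlap ratios (``None`` where undefined)."""
    tp: int
    fp: int
    fn: int
    tn: int

    def _ratio(self, num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    @property
    def jaccard(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp + self.fn)

    @property
    def dice(self) -> Optional[float]:
        return self._ratio(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    @property
    def tpr(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def fpr(self) -> Optional[float]:
        return self._ratio(self.fp, self.fp + self.tn)

    @property
    def fnr(self) -> Optional[float]:
        return self._ratio(self.fn, self.tp + self.fn)


def binary_metrics(pred: np.ndarray, truth: np.ndarray) -> EvalMetrics:
    """Confusion counts and overlap ratios of two aligned boolean masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    if pred.dtype != np.bool_ or truth.dtype != np.bool_:
        raise InputError("binary_metrics expects boolean masks")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return EvalMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class ConfusionMatrix:
    """K-class confusion matrix; rows are true classes, columns predicted."""
    labels: Tuple[str, ...]
    counts: np.ndarray  # (K, K) int

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise InputError(f"counts shape {self.counts.shape} does not match "
                             f"{k} labels")
        if (self.counts < 0).any():
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def recall(self, label: str) -> Optional[float]:
        i = self._index(label)
        row = self.counts[i].sum()
        return float(self.counts[i, i]) / row if row > 0 else None

    def precision(self, label: str) -> Optional[float]:
        j = self._index(label)
        col = self.counts[:, j].sum()
        return float(self.counts[j, j]) / col if col > 0 else None

    def _index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"unknown label {label!r}; known: {self.labels}") from None


def confusion_matrix(true_labels: Sequence, pred_labels: Sequence,
                     labels: Sequence[str]) -> ConfusionMatrix:
    """Count (true, predicted) label pairs into a K x K matrix with the
    given class order."""
    if len(true_labels) != len(pred_labels):
        raise InputError("true and predicted label sequences differ in length")
    labels = tuple(str(v) for v in labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        t, p = str(t), str(p)
        if t not in index or p not in index:
            raise InputError(f"label pair ({t!r}, {p!r}) outside known labels {labels}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def read_confusion_csv(path) -> ConfusionMatrix:
    """Read a confusion matrix stored as CSV with a leading label column
    (and either a header row of predicted labels or none)."""
    df = pd.read_csv(path, index_col=0)
    labels = tuple(str(v) for v in df.index)
    return ConfusionMatrix(labels=labels, counts=df.to_numpy())


# ---------------------------------------------------------------------------
# benchmark tables
# ---------------------------------------------------------------------------

_COLUMNS = ("image", "method", "jaccard", "dice", "fpr", "fnr")


def _round4(v: Optional[float]) -> Optional[float]:
    return None if v is None else round(float(v), 4)


def benchmark_table(results: List[Tuple[str, str, EvalMetrics]]) -> pd.DataFrame:
    """One row per (image, method) with jaccard/dice/fpr/fnr to 4
    decimals, followed by one per-method median row (image = "median").
    Undefined metrics stay missing (rendered "NA" on write)."""
    if not results:
        raise InputError("benchmark_table: empty result list")
    rows = []
    for image_id, method, m in results:
        rows.append({"image": str(image_id), "method": str(method),
                     "jaccard": _round4(m.jaccard), "dice": _round4(m.dice),
                     "fpr": _round4(m.fpr), "fnr": _round4(m.fnr)})
    df = pd.DataFrame(rows, columns=list(_COLUMNS))
    medians = []
    for method, grp in df.groupby("method", sort=True):
        med = {"image": "median", "method": method}
        for col in ("jaccard", "dice", "fpr", "fnr"):
            vals = grp[col].dropna()
            med[col] = _round4(float(vals.median())) if len(vals) else None
        medians.append(med)
    return pd.concat([df, pd.DataFrame(medians, columns=list(_COLUMNS))],
                     ignore_index=True)


def write_benchmark_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), index=False, na_rep="NA")


def write_benchmark_json(table: pd.DataFrame, path) -> None:
    records = []
    for _, row in table.iterrows():
        rec = {}
        for col in _COLUMNS:
            v = row[col]
            rec[col] = None if (v is None or (isinstance(v, float) and np.isnan(v))) else v
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
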