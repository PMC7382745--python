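"""Multitask loss and segmentation metrics.

The training objective is the unweighted sum over the four tasks of a
categorical cross entropy between the two-plane probability prediction and
the two-plane encoded target, averaged over the batch and over pixels and
summed over the n = 2 categories.  Evaluation reports the Dice similarity
coefficient (DSC), precision, recall and the Jaccard index per case and task,
aggregated as mean and sample standard deviation over cases.

Conventions worth knowing:

* predictions are clamped at ``eps = 1e-7`` before the log;
* a case/task where both the prediction and the truth are empty scores 1.0 on
  all four metrics (an all-background task is a perfect segmentation of
  nothing — phantoms can legitimately produce such cases);
* ``Std`` columns use the sample (n-1) standard deviation, 0.0 for a single row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, add, cross_entropy
from .codec import TASK_NAMES, MaskValidationError, _check_binary

__all__ = ["SegScores", "MetricsTable", "task_loss", "total_loss", "score_pair", "aggregate"]

LOG_EPS = 1e-7
METRIC_NAMES = ("dsc", "precision", "recall", "jaccard")


def task_loss(pred, target, eps: float = LOG_EPS):
    """Categorical cross entropy of one task over a batch.

    ``pred``: probabilities of shape (N, 2, H, W) — a Tensor during training
    (the return value participates in backprop) or a plain array (a float is
    returned).  ``target``: encoded mask batch of the same shape.
    """
    is_tensor = isinstance(pred, Tensor)
    pred_t = pred if is_tensor else Tensor(np.asarray(pred))
    target = np.asarray(target, dtype=pred_t.data.dtype)
    if target.shape != pred_t.data.shape:
        raise ValueError(f"task_loss: target shape {target.shape} != prediction shape {pred_t.data.shape}")
    if pred_t.data.ndim != 4 or pred_t.data.shape[1] != 2:
        raise ValueError(f"task_loss expects (N, 2, H, W) inputs, got {pred_t.data.shape}")
    out = cross_entropy(pred_t, target, eps=eps)
    return out if is_tensor else float(out.data)


def total_loss(per_task):
    """Unweighted sum of the four per-task losses, in fixed task order."""
    per_task = list(per_task)
    if len(per_task) != len(TASK_NAMES):
        raise ValueError(f"total_loss expects {len(TASK_NAMES)} task losses, got {len(per_task)}")
    if any(isinstance(t, Tensor) for t in per_task):
        acc = per_task[0] if isinstance(per_task[0], Tensor) else Tensor(np.asarray(per_task[0]))
        for t in per_task[1:]:
            acc = add(acc, t)
        return acc
    acc = per_task[0]
    for t in per_task[1:]:
        acc = acc + t
    return acc


@dataclass(frozen=True)
class SegScores:
    """Overlap scores of one predicted mask against its ground truth."""

    tp: int
    fp: int
    fn: int
    dsc: float
    precision: float
    recall: float
    jaccard: float


def score_pair(pred_mask, truth) -> SegScores:
    """DSC, precision, recall and Jaccard of a binary prediction vs truth."""
    p = _check_binary(pred_mask, "pred_mask")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise MaskValidationError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t & 1))
    fn = int(np.count_nonzero(~p & 1 & t))
    if tp + fp + fn == 0:
        # both masks empty: perfect agreement by convention
        return SegScores(tp=0, fp=0, fn=0, dsc=1.0, precision=1.0, recall=1.0, jaccard=1.0)
    dsc = 2.0 * tp / (2.0 * tp + fp + fn)
    jac = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if tp + fn else (1.0 if fp == 0 else 0.0)
    return SegScores(tp=tp, fp=fp, fn=fn, dsc=dsc, precision=precision,
                     recall=recall, jaccard=jac)


class MetricsTable:
    """Per-(case, task) scores plus a per-task mean/Std aggregate block."""

    def __init__(self, rows: pd.DataFrame, aggregate_block: pd.DataFrame):
        self.rows = rows
        self.aggregate = aggregate_block

    def to_csv(self, path):
        with open(path, "w") as fh:
            self.rows.to_csv(fh, index=False)
            fh.write("# aggregate\n")
            self.aggregate.to_csv(fh, index=False)

    def task_mean(self, task, metric="dsc") -> float:
        sel = self.aggregate[(self.aggregate["task"] == task)
                             & (self.aggregate["statistic"] == "mean")]
        return float(sel[metric].iloc[0])


def aggregate(rows) -> MetricsTable:
    """Aggregate (case, task, SegScores) rows into per-task mean and Std.

    Averaging is per image (one row per case), never pooled over pixels.
    """
    records = [
        {"case": case, "task": task, **{m: getattr(s, m) for m in METRIC_NAMES}}
        for case, task, s in rows
    ]
    if not records:
        raise ValueError("aggregate requires at least one row")
    df = pd.DataFrame.from_records(records)
    present = set(df["task"])
    ordered = [t for t in TASK_NAMES if t in present]
    ordered += sorted(present - set(TASK_NAMES))
    agg_rows = []
    for task in ordered:
        sub = df[df["task"] == task]
        if sub.empty:
            raise ValueError(f"aggregate: no rows for task '{task}'")
        for stat in ("mean", "std"):
            rec = {"task": task, "statistic": stat}
            for m in METRIC_NAMES:
                vals = sub[m].to_numpy(dtype=float)
                rec[m] = float(vals.mean()) if stat == "mean" else (
                    float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
            agg_rows.append(rec)
    return MetricsTable(df, pd.DataFrame.from_records(agg_rows))
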