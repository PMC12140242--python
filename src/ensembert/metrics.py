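"""Evaluation at three granularities: item, overall score, severity category.

Item level treats every (user, item) pair as one observation on the 0-3
scale (MAE, MSE).  Overall level compares the per-user sums on the 0-63
scale (MAE, RMSE).  Category level compares the four severity bands with
accuracy, support-weighted F1, the squared category distance
``MSE_category = mean (c - c_hat)^2``, and a 4x4 confusion matrix.  A
majority-class baseline (constant modal category) anchors the category
metrics against class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .questionnaire import SEVERITY_LABELS, Severity

N_CATEGORIES = 4


class MetricsError(ValueError):
    pass


def _align(true: Mapping | Sequence, pred: Mapping | Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Align two score collections; mappings are matched by key."""
    if isinstance(true, Mapping) or isinstance(pred, Mapping):
        if not (isinstance(true, Mapping) and isinstance(pred, Mapping)):
            raise MetricsError("either both or neither input may be a mapping")
        if set(true) != set(pred):
            missing = set(true) ^ set(pred)
            raise MetricsError(f"misaligned keys, e.g. {sorted(missing, key=str)[:5]}")
        keys = sorted(true, key=str)
        return (np.array([true[k] for k in keys], dtype=float),
                np.array([pred[k] for k in keys], dtype=float))
    t = np.asarray(list(true), dtype=float)
    p = np.asarray(list(pred), dtype=float)
    if t.shape != p.shape:
        raise MetricsError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise MetricsError("empty inputs")
    return t, p


def item_level(true, pred) -> tuple[float, float]:
    """MAE and MSE over aligned (user, item) score pairs."""
    t, p = _align(true, pred)
    err = t - p
    return float(np.mean(np.abs(err))), float(np.mean(err**2))


def overall_level(true, pred) -> tuple[float, float]:
    """MAE and RMSE over aligned per-user overall scores."""
    t, p = _align(true, pred)
    err = t - p
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


@dataclass(frozen=True)
class CategoryMetrics:
    accuracy: float
    f1_weighted: float
    mse_category: float
    confusion: np.ndarray  # 4x4, rows = true
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray


def confusion_matrix(true_cats: Sequence[int], pred_cats: Sequence[int]) -> np.ndarray:
    t = np.asarray([int(c) for c in true_cats])
    p = np.asarray([int(c) for c in pred_cats])
    if t.shape != p.shape or t.size == 0:
        raise MetricsError("category inputs must be non-empty and aligned")
    if np.any((t < 0) | (t >= N_CATEGORIES)) or np.any((p < 0) | (p >= N_CATEGORIES)):
        raise MetricsError("categories must be in 0..3")
    cm = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def category_level(true_cats, pred_cats, average: str = "weighted") -> CategoryMetrics:
    """Accuracy, F1, squared category distance, and confusion matrix.

    Per-class F1 is 2PR/(P+R), defined as 0 when P+R is 0; ``average``
    selects support-weighted (default, matching class-imbalanced reporting)
    or macro averaging.
    """
    t = np.asarray([int(c) for c in true_cats])
    p = np.asarray([int(c) for c in pred_cats])
    cm = confusion_matrix(t, p)
    n = cm.sum()
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)
    pred_count = cm.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_count > 0, tp / pred_count, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if average == "weighted":
        f1_avg = float(np.sum(f1 * support) / n)
    elif average == "macro":
        f1_avg = float(np.mean(f1))
    else:
        raise MetricsError(f"unknown average {average!r}")
    return CategoryMetrics(
        accuracy=float(tp.sum() / n),
        f1_weighted=f1_avg,
        mse_category=float(np.mean((t - p) ** 2)),
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def majority_baseline(
    true_cats: Sequence[int], train_cats: Sequence[int] | None = None
) -> tuple[Severity, float]:
    """Constant modal-category predictor and its accuracy.

    The mode is taken from ``train_cats`` when given (otherwise from the
    evaluation labels themselves); ties break toward the lower severity.
    The accuracy equals the modal category's relative frequency among the
    evaluation labels.
    """
    t = np.asarray([int(c) for c in true_cats])
    if t.size == 0:
        raise MetricsError("need at least one label")
    source = t if train_cats is None else np.asarray([int(c) for c in train_cats])
    counts = np.bincount(source, minlength=N_CATEGORIES)
    mode = int(np.argmax(counts))  # first maximizer = lowest severity on ties
    return Severity(mode), float(np.mean(t == mode))


@dataclass(frozen=True)
class EvaluationReport:
    """All metrics of one evaluation run."""

    mae_item: float
    mse_item: float
    mae_overall: float
    rmse_overall: float
    acc_category: float
    f1_category_weighted: float
    mse_category: float
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    baseline_category: Severity
    baseline_accuracy: float
    n_users: int
    n_item_pairs: int

    def to_dict(self) -> dict:
        return {
            "mae_item": self.mae_item,
            "mse_item": self.mse_item,
            "mae_overall": self.mae_overall,
            "rmse_overall": self.rmse_overall,
            "acc_category": self.acc_category,
            "f1_category_weighted": self.f1_category_weighted,
            "mse_category": self.mse_category,
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "baseline_category": self.baseline_category.label,
            "baseline_accuracy": self.baseline_accuracy,
            "n_users": self.n_users,
            "n_item_pairs": self.n_item_pairs,
        }

    def to_table(self, ndigits: int = 3) -> str:
        """Human-readable one-row table of the headline metrics."""
        cols = [
            ("MAE_item", self.mae_item),
            ("MSE_item", self.mse_item),
            ("MAE_overall", self.mae_overall),
            ("RMSE_overall", self.rmse_overall),
            ("ACC_category", self.acc_category),
            ("F1_category", self.f1_category_weighted),
            ("MSE_category", self.mse_category),
        ]
        header = "\t".join(name for name, _ in cols)
        row = "\t".join(f"{val:.{ndigits}f}" for _, val in cols)
        return f"{header}\n{row}"


def evaluation_report(
    item_true: Mapping,
    item_pred: Mapping,
    overall_true: Mapping,
    overall_pred: Mapping,
    cat_true: Mapping,
    cat_pred: Mapping,
    train_cats: Sequence[int] | None = None,
) -> EvaluationReport:
    """Assemble the full three-granularity report from aligned mappings."""
    mae_i, mse_i = item_level(item_true, item_pred)
    mae_o, rmse_o = overall_level(overall_true, overall_pred)
    users = sorted(cat_true, key=str)
    if set(users) != set(cat_pred):
        raise MetricsError("category mappings are misaligned")
    t_cats = [int(cat_true[u]) for u in users]
    p_cats = [int(cat_pred[u]) for u in users]
    cat = category_level(t_cats, p_cats)
    base_cat, base_acc = majority_baseline(t_cats, train_cats=train_cats)
    return EvaluationReport(
        mae_item=mae_i,
        mse_item=mse_i,
        mae_overall=mae_o,
        rmse_overall=rmse_o,
        acc_category=cat.accuracy,
        f1_category_weighted=cat.f1_weighted,
        mse_category=cat.mse_category,
        confusion=cat.confusion,
        precision=cat.precision,
        recall=cat.recall,
        f1=cat.f1,
        baseline_category=base_cat,
        baseline_accuracy=base_acc,
        n_users=len(users),
        n_item_pairs=len(item_true),
    )
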