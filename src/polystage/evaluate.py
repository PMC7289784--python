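"""Agreement metrics for sleep staging.

Covers the full reporting scheme: 5×5 confusion matrix (rows = expert,
columns = model), per-stage precision/recall/F1, count-weighted averages
(predicted-count-weighted precision is identically the overall accuracy,
Σ TPᵢ / N), Cohen's Kappa, top-k accuracy with a fixed-stage-order
tie-break, the top-2 increase rate, the second-choice distribution table,
AHI severity stratification, and total sleep time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io import Hypnogram, STAGES, STAGE_INDEX

AHI_SEVERITY_CLASSES = ("normal", "mild", "moderate", "severe")


class AlignmentError(ValueError):
    pass


def _as_indices(labels) -> np.ndarray:
    if isinstance(labels, Hypnogram):
        return labels.indices()
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.array([STAGE_INDEX[str(l)] for l in arr], dtype=np.int64)


# ---------------------------------------------------------------------------
# Confusion matrix and derived per-class metrics
# ---------------------------------------------------------------------------

def confusion(true, pred) -> np.ndarray:
    """5×5 counts; rows = expert label, columns = predicted label."""
    t, p = _as_indices(true), _as_indices(pred)
    if len(t) != len(p):
        raise AlignmentError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    return _sk_confusion(t, p, labels=np.arange(len(STAGES)))


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); defined as 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def per_class_metrics(cm: np.ndarray) -> pd.DataFrame:
    """Precision/recall/F1 plus true and predicted counts per stage."""
    cm = np.asarray(cm, dtype=np.int64)
    tp = np.diag(cm).astype(np.float64)
    pred_count = cm.sum(axis=0).astype(np.float64)
    true_count = cm.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_count > 0, tp / pred_count, 0.0)
        recall = np.where(true_count > 0, tp / true_count, 0.0)
    f1 = np.array([f1_from_pr(p, r) for p, r in zip(precision, recall)])
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "predicted_count": pred_count.astype(np.int64),
            "true_count": true_count.astype(np.int64),
        },
        index=list(STAGES),
    )


def weighted_metrics(values: np.ndarray, weights: np.ndarray) -> float:
    """Count-weighted average of a per-class metric column.

    With per-class precision weighted by predicted-class counts this
    reproduces overall accuracy exactly (Σ TPᵢ / N).
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.sum() <= 0:
        raise ValueError("total weight must be positive")
    return float((values * weights).sum() / weights.sum())


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=np.float64)
    return float(np.diag(cm).sum() / cm.sum())


def cohens_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement from the confusion matrix marginals."""
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.diag(cm).sum() / n
    p_e = float((cm.sum(axis=0) / n) @ (cm.sum(axis=1) / n))
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))


# ---------------------------------------------------------------------------
# Top-k accuracy
# ---------------------------------------------------------------------------

def topk_sets(probs: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most probable stages per epoch, ties broken by the
    fixed stage order W < N1 < N2 < N3 < R (stable sort on descending p)."""
    probs = np.asarray(probs, dtype=np.float64)
    order = np.argsort(-probs, axis=1, kind="stable")
    return order[:, :k]


def topk_accuracy(true, probs: np.ndarray, k: int = 2) -> float:
    """Fraction of epochs whose true label is among the k most probable."""
    t = _as_indices(true)
    probs = np.asarray(probs, dtype=np.float64)
    if len(t) != len(probs):
        raise AlignmentError(f"length mismatch: {len(t)} labels vs {len(probs)} prob rows")
    if not (1 <= k <= probs.shape[1]):
        raise ValueError(f"k must be in 1..{probs.shape[1]}")
    top = topk_sets(probs, k)
    return float(np.mean([t[i] in top[i] for i in range(len(t))]))


def increase_rate(top1: float, top2: float) -> float:
    """Top-2 accuracy gain over top-1 (the ambiguity headroom)."""
    if top2 < top1:
        raise ValueError("top-2 accuracy cannot be below top-1")
    return top2 - top1


# ---------------------------------------------------------------------------
# Second-choice distribution (pre-expert-rule predictions)
# ---------------------------------------------------------------------------

def second_choice_table(probs: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and percentages of (top-1, top-2) stage pairs.

    Cell (i, j): epochs predicted i whose runner-up is j, as a count and as
    a percentage of all epochs predicted i.  The diagonal is undefined (NaN).
    """
    top2 = topk_sets(np.asarray(probs), 2)
    counts = np.zeros((5, 5), dtype=np.int64)
    for a, b in top2:
        counts[a, b] += 1
    pred_totals = counts.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(pred_totals[:, None] > 0,
                       100.0 * counts / pred_totals[:, None], 0.0)
    pct = pct.astype(np.float64)
    np.fill_diagonal(pct, np.nan)
    idx = list(STAGES)
    return (pd.DataFrame(counts, index=idx, columns=idx),
            pd.DataFrame(pct, index=idx, columns=idx))


# ---------------------------------------------------------------------------
# AHI stratification and summary quantities
# ---------------------------------------------------------------------------

def ahi_class(ahi: float) -> str:
    """OSA severity from AHI: <5 normal, 5–15 mild, 15–30 moderate, ≥30 severe."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def estimate_tst(hypnogram: Hypnogram) -> float:
    """Total sleep time in minutes: non-wake epochs × epoch length."""
    n_sleep = sum(1 for l in hypnogram.labels if l != "W")
    return n_sleep * hypnogram.epoch_s / 60.0


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Everything the reporting scheme computes, for one epoch collection."""

    confusion_matrix: np.ndarray
    per_class: pd.DataFrame
    accuracy: float
    weighted_precision: float
    weighted_f1: float
    kappa: float
    top1_acc: float
    top2_acc: float
    increase_rate: float
    n_epochs: int
    by_severity: pd.DataFrame | None = None
    second_choice_counts: pd.DataFrame | None = None
    second_choice_pct: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_f1": self.weighted_f1,
            "kappa": self.kappa,
            "top1_acc": self.top1_acc,
            "top2_acc": self.top2_acc,
            "increase_rate": self.increase_rate,
            "n_epochs": self.n_epochs,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class": {
                s: {k: float(v) for k, v in row.items()}
                for s, row in self.per_class.iterrows()
            },
        }
        if self.by_severity is not None:
            out["by_severity"] = {
                s: {k: float(v) for k, v in row.items()}
                for s, row in self.by_severity.iterrows()
            }
        return out

    def summary(self, decimals: int = 4) -> str:
        """Plain-text metric block; values rounded half-even for display."""
        r = lambda x: format(np.round(x, decimals), f".{decimals}f")
        lines = [
            f"epochs evaluated : {self.n_epochs}",
            f"accuracy         : {r(self.accuracy)}",
            f"weighted F1      : {r(self.weighted_f1)}",
            f"Cohen's kappa    : {r(self.kappa)}",
            f"top-1 / top-2    : {r(self.top1_acc)} / {r(self.top2_acc)}"
            f"  (increase rate {r(self.increase_rate)})",
        ]
        return "\n".join(lines)


def evaluate(
    true,
    pred,
    probs: np.ndarray | None = None,
    ahi_per_epoch: np.ndarray | None = None,
) -> EvaluationReport:
    """Assemble the full report for one set of epochs.

    ``probs`` (integrated per-epoch probabilities) enables the top-2 block;
    ``ahi_per_epoch`` (each epoch's record AHI) enables the severity
    stratification.
    """
    t, p = _as_indices(true), _as_indices(pred)
    cm = confusion(t, p)
    pc = per_class_metrics(cm)
    acc = accuracy(cm)
    w_prec = weighted_metrics(pc["precision"].values, pc["predicted_count"].values)
    w_f1 = weighted_metrics(pc["f1"].values, pc["predicted_count"].values)
    kap = cohens_kappa(cm)

    top1 = float((t == p).mean())
    top2 = top1
    sc_counts = sc_pct = None
    if probs is not None:
        top1_p = topk_accuracy(t, probs, k=1)
        top2 = topk_accuracy(t, probs, k=2)
        top1 = top1_p
        sc_counts, sc_pct = second_choice_table(probs)

    by_sev = None
    if ahi_per_epoch is not None:
        ahi_per_epoch = np.asarray(ahi_per_epoch, dtype=np.float64)
        if len(ahi_per_epoch) != len(t):
            raise AlignmentError("ahi_per_epoch length mismatch")
        sev = np.array([ahi_class(a) for a in ahi_per_epoch])
        rows = {}
        for cls in AHI_SEVERITY_CLASSES:
            sel = sev == cls
            if not sel.any():
                continue
            cm_s = confusion(t[sel], p[sel])
            pc_s = per_class_metrics(cm_s)
            row = {
                "accuracy": accuracy(cm_s),
                "weighted_f1": weighted_metrics(
                    pc_s["f1"].values, pc_s["predicted_count"].values),
                "kappa": cohens_kappa(cm_s),
                "n_epochs": int(sel.sum()),
            }
            if probs is not None:
                row["top1_acc"] = topk_accuracy(t[sel], probs[sel], k=1)
                row["top2_acc"] = topk_accuracy(t[sel], probs[sel], k=2)
                row["increase_rate"] = row["top2_acc"] - row["top1_acc"]
            rows[cls] = row
        by_sev = pd.DataFrame(rows).T

    return EvaluationReport(
        confusion_matrix=cm,
        per_class=pc,
        accuracy=acc,
        weighted_precision=w_prec,
        weighted_f1=w_f1,
        kappa=kap,
        top1_acc=top1,
        top2_acc=top2,
        increase_rate=top2 - top1,
        n_epochs=len(t),
        by_severity=by_sev,
        second_choice_counts=sc_counts,
        second_choice_pct=sc_pct,
    )
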