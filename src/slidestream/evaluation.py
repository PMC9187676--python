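"""Diagnostic-accuracy statistics for node- and slide-level classification.

Confusion-matrix metrics (sensitivity, specificity, PPV, NPV, accuracy,
Matthews correlation coefficient), exact binomial (Clopper-Pearson)
confidence limits, ROC/AUC with DeLong variance and the paired DeLong test,
max-aggregation of node scores to slide scores, operating-threshold
selection by MCC, and the coefficient of variation of repeated counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta, norm, rankdata

UNDEFINED = None  # marker returned for metrics with a zero denominator


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise EvaluationError("confusion matrix is all zero")

    @classmethod
    def from_labels(cls, pred, truth) -> "ConfusionMatrix":
        pred = np.asarray(pred, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        return cls(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
            tn=int(np.sum(~pred & ~truth)),
        )


def _ratio(num, den):
    return num / den if den > 0 else UNDEFINED


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Standard confusion-matrix metrics; zero-denominator metrics are None.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); by common
    convention MCC is 0 when its denominator vanishes.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "accuracy": (tp + tn) / (tp + fp + fn + tn),
        "mcc": mcc,
    }


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if n < 1 or not (0 <= x <= n):
        raise EvaluationError(f"invalid successes/trials ({x}, {n})")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


@dataclass
class ScoreTable:
    """Per-instance prediction records: (instance id, group id, score, label)."""

    instance_ids: np.ndarray
    group_ids: np.ndarray
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.instance_ids = np.asarray(self.instance_ids)
        self.group_ids = np.asarray(self.group_ids)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.scores)
        if not (len(self.instance_ids) == len(self.group_ids) == len(self.labels) == n):
            raise EvaluationError("score-table columns must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise EvaluationError("scores must be finite")
        if np.any((self.labels != 0) & (self.labels != 1)):
            raise EvaluationError("labels must be binary")

    def __len__(self):
        return len(self.scores)

    @classmethod
    def from_records(cls, records) -> "ScoreTable":
        ids, groups, scores, labels = zip(*records)
        return cls(np.array(ids), np.array(groups), np.array(scores), np.array(labels))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path)
        return cls(
            df["instance_id"].to_numpy(),
            df["slide_id"].to_numpy(),
            df["score"].to_numpy(),
            df["label"].to_numpy(),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "instance_id": self.instance_ids,
                "slide_id": self.group_ids,
                "score": self.scores,
                "label": self.labels,
            }
        ).to_csv(path, index=False)


def roc_auc(table: ScoreTable) -> float:
    """AUC by the Mann-Whitney U formulation; ties credited 0.5."""
    pos = table.scores[table.labels == 1]
    neg = table.scores[table.labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("both classes must be present for ROC analysis")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if x == y, 0 otherwise, vectorized by midranks
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    return auc, v10, v01


def delong(table_a: ScoreTable, table_b: ScoreTable | None = None, level: float = 0.95) -> dict:
    """DeLong AUC variance, Wald CI, and the paired two-sided test.

    With one table: ``{"auc", "variance", "ci"}``.  With two tables sharing
    instance ids: per-table AUCs/variances plus ``delta_auc`` and the paired
    two-sided ``p_value`` for the AUC difference.
    """
    auc_a, v10_a, v01_a = _delong_components(table_a.scores, table_a.labels)
    m, n = len(v10_a), len(v01_a)
    var_a = (np.var(v10_a, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01_a, ddof=1) / n if n > 1 else 0.0
    )
    z = norm.ppf(1 - (1 - level) / 2)
    half = z * math.sqrt(var_a)
    out = {
        "auc": auc_a,
        "variance": var_a,
        "ci": (max(0.0, auc_a - half), min(1.0, auc_a + half)),
    }
    if table_b is None:
        return out
    order_a = np.argsort(table_a.instance_ids, kind="stable")
    order_b = np.argsort(table_b.instance_ids, kind="stable")
    if not np.array_equal(table_a.instance_ids[order_a], table_b.instance_ids[order_b]) or not (
        np.array_equal(table_a.labels[order_a], table_b.labels[order_b])
    ):
        raise EvaluationError("paired DeLong test requires matching instance ids and labels")
    sa, sb = table_a.scores[order_a], table_b.scores[order_b]
    lab = table_a.labels[order_a]
    auc_a, v10_a, v01_a = _delong_components(sa, lab)
    auc_b, v10_b, v01_b = _delong_components(sb, lab)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2 * norm.sf(abs(delta) / math.sqrt(var_diff)))
    out.update(
        auc_b=auc_b,
        variance_b=float(cov[1, 1]),
        variance=float(cov[0, 0]),
        delta_auc=float(delta),
        p_value=p,
    )
    return out


def slide_score(ln_scores) -> float:
    """Slide-level score: maximum over its node scores."""
    ln_scores = np.asarray(ln_scores, dtype=np.float64)
    if ln_scores.size == 0:
        raise EvaluationError("cannot aggregate an empty score list")
    return float(ln_scores.max())


def classify(table: ScoreTable, threshold: float) -> np.ndarray:
    """Binary labels: positive iff score >= threshold (inclusive rule)."""
    if not (0.0 <= threshold <= 1.0):
        raise EvaluationError("threshold must be in [0, 1]")
    return (table.scores >= threshold).astype(int)


def pick_threshold_mcc(table: ScoreTable, grid) -> float:
    """Grid threshold maximizing MCC; ties resolve to the smallest threshold."""
    grid = sorted(float(t) for t in grid)
    if len(np.unique(table.labels)) < 2:
        warnings.warn("single-class truth: falling back to the smallest grid threshold")
        return grid[0]
    best_t, best_mcc = grid[0], -np.inf
    for t in grid:
        cm = ConfusionMatrix.from_labels(table.scores >= t, table.labels == 1)
        mcc = confusion_metrics(cm)["mcc"]
        if mcc > best_mcc:
            best_t, best_mcc = t, mcc
    return best_t


def count_cv(counts) -> float:
    """Coefficient of variation of raters' counts (unbiased variance, n-1).

    0 when all counts are equal, including the all-zero case.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size < 2:
        raise EvaluationError("coefficient of variation needs at least 2 counts")
    if np.any(counts < 0):
        raise EvaluationError("counts must be non-negative")
    if np.all(counts == counts[0]):
        return 0.0
    return float(np.std(counts, ddof=1) / np.mean(counts))
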