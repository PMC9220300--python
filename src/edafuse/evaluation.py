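"""Leave-one-subject-out protocol, classification metrics, significance tests.

Evaluation follows the subject-independent protocol standard in affective
computing: each participant's trials form one test fold while every other
participant's trials train the model, so reported accuracy reflects
generalization to unseen people. Methods are compared across folds with the
nonparametric Friedman rank test, followed by the Nemenyi post-hoc procedure
whose critical distance is

    CD = q_alpha * sqrt(k (k + 1) / (6 N))

for k methods compared over N result groups, with q_alpha from the
studentized-range distribution (divided by sqrt(2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = [
    "FoldResult",
    "EvalReport",
    "loso_folds",
    "compute_metrics",
    "friedman_test",
    "nemenyi_q_alpha",
    "nemenyi_cd",
]


def loso_folds(subject_ids) -> list[tuple[list, object]]:
    """Leave-one-subject-out folds: (training subjects, held-out subject) pairs.

    Accepts an iterable of unique subject identifiers and returns one fold
    per subject; the test subjects across folds partition the subject set.
    """
    subjects = list(dict.fromkeys(subject_ids))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in subjects if s != held], held) for held in subjects]


def compute_metrics(y_true, y_pred, positive_class) -> dict[str, float]:
    """Recall, precision, accuracy and F1 for a binary prediction vector.

    Ratios with zero denominators (e.g. no predicted positives) are reported
    as 0 with a warning. The confusion-matrix counts are included so metrics
    can be recomputed exactly from the report.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    tp = int(np.sum((y_true == positive_class) & (y_pred == positive_class)))
    fp = int(np.sum((y_true != positive_class) & (y_pred == positive_class)))
    fn = int(np.sum((y_true == positive_class) & (y_pred != positive_class)))
    tn = int(np.sum((y_true != positive_class) & (y_pred != positive_class)))

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    accuracy = ratio(tp + tn, tp + fp + fn + tn, "accuracy")
    f1 = ratio(2 * precision * recall, precision + recall, "F1")
    return {
        "recall": recall, "precision": precision, "accuracy": accuracy, "f1": f1,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


@dataclass
class FoldResult:
    """Metrics and confusion matrix for one held-out subject."""

    test_subject: object
    metrics: dict[str, float]


@dataclass
class EvalReport:
    """Per-fold results with per-fold-averaged aggregates."""

    folds: list[FoldResult] = field(default_factory=list)

    def aggregate(self) -> dict[str, float]:
        """Mean of each metric across folds plus the accuracy standard deviation."""
        out: dict[str, float] = {}
        for m in ("recall", "precision", "accuracy", "f1"):
            vals = np.array([f.metrics[m] for f in self.folds])
            out[m] = float(vals.mean())
        out["accuracy_sd"] = float(
            np.std([f.metrics["accuracy"] for f in self.folds])
        )
        return out

    def pooled(self) -> dict[str, float]:
        """Metrics recomputed from the pooled confusion matrix over all folds."""
        tp = sum(f.metrics["tp"] for f in self.folds)
        fp = sum(f.metrics["fp"] for f in self.folds)
        fn = sum(f.metrics["fn"] for f in self.folds)
        tn = sum(f.metrics["tn"] for f in self.folds)
        total = tp + fp + fn + tn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        return {
            "recall": recall,
            "precision": precision,
            "accuracy": (tp + tn) / total if total else 0.0,
            "f1": (2 * precision * recall / (precision + recall)
                   if precision + recall else 0.0),
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        }

    def to_dict(self) -> dict:
        return {
            "folds": [
                {"test_subject": str(f.test_subject), **f.metrics} for f in self.folds
            ],
            "aggregate": self.aggregate(),
        }


def friedman_test(results: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over an N×k matrix (N result groups, k methods).

    Scores are ranked within each group (ties get mean ranks); the
    chi-square statistic with the standard tie correction is referred to a
    chi-square distribution with k−1 degrees of freedom. Identical columns
    yield statistic 0 and p-value 1.
    """
    results = np.asarray(results, dtype=float)
    if results.ndim != 2:
        raise ValueError("results must be an N×k matrix")
    n, k = results.shape
    if n < 2 or k < 2:
        raise ValueError(f"need N >= 2 groups and k >= 2 methods, got {results.shape}")
    if not np.all(np.isfinite(results)):
        raise ValueError("results contains missing/non-finite cells")
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, results)
    rank_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(rank_sums**2))
    stat = 12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)
    # Tie correction: within each group, sum t^3 - t over tie blocks.
    ties = 0.0
    for row in results:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c == 0.0:
        return 0.0, 1.0
    stat /= c
    stat = max(stat, 0.0)
    p = float(scipy.stats.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return float(stat), p


def nemenyi_q_alpha(k: int, alpha: float = 0.05) -> float:
    """Critical value q_alpha for the Nemenyi test with k methods.

    Computed from the studentized-range distribution with infinite degrees
    of freedom divided by sqrt(2); reproduces the standard table (e.g.
    k=5, alpha=0.05 -> 2.728).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    return float(scipy.stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2))


def nemenyi_cd(k: int, n_groups: int, q_alpha: float | None = None,
               alpha: float = 0.05) -> float:
    """Nemenyi critical distance CD = q_alpha * sqrt(k (k+1) / (6 N)).

    Two methods whose mean ranks differ by more than CD over the N groups
    are significantly different at level alpha.
    """
    if k < 2 or n_groups < 1:
        raise ValueError(f"need k >= 2 and N >= 1, got k={k}, N={n_groups}")
    if q_alpha is None:
        q_alpha = nemenyi_q_alpha(k, alpha)
    if q_alpha <= 0:
        raise ValueError("q_alpha must be > 0")
    return float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * n_groups)))
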