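"""Diagnostic-accuracy and proportion inference.

Sensitivity/specificity with Clopper–Pearson exact binomial confidence
intervals, ROC curves and AUC under the package's decision convention
(``score >= t`` is positive), Youden's optimal cut-point, and crude
monthly prevalence with logit-scale confidence intervals (exact fallback
at the boundaries x = 0 and x = n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .features import ScoringModel, classify_many, score_many
from .records import PresentationRecord


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class Estimate(NamedTuple):
    """Point estimate with a two-sided confidence interval."""

    point: float
    lo: float
    hi: float


def clopper_pearson(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial CI via beta quantiles.

    ``x = 0`` gives a lower bound of 0; ``x = n`` an upper bound of 1.
    """
    if not 0 <= x <= n or n <= 0:
        raise ValueError(f"need 0 <= x <= n with n > 0, got x={x}, n={n}")
    alpha = 1.0 - conf_level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def sens_spec(
    counts: ConfusionCounts, conf_level: float = 0.95
) -> tuple[Estimate, Estimate]:
    """Sensitivity and specificity with exact binomial CIs."""
    if counts.tp + counts.fn == 0:
        raise ValueError("no positives: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negatives: specificity undefined")
    se = counts.tp / (counts.tp + counts.fn)
    sp = counts.tn / (counts.tn + counts.fp)
    se_ci = clopper_pearson(counts.tp, counts.tp + counts.fn, conf_level)
    sp_ci = clopper_pearson(counts.tn, counts.tn + counts.fp, conf_level)
    return Estimate(se, *se_ci), Estimate(sp, *sp_ci)


def _check_two_class(labels: np.ndarray) -> None:
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("both classes must be present")


def roc_points(scores, labels) -> np.ndarray:
    """ROC points [(fpr, tpr)] over all distinct thresholds, score >= t positive.

    The first point is (0, 0) (threshold above every score) and the last
    is (1, 1) (threshold at the minimum score); thresholds descend.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_class(labels)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    thresholds = np.unique(scores)[::-1]
    tpr = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg, thresholds, side="left") / neg.size
    pts = np.column_stack([np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])])
    return pts


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC (ties counted half, Mann–Whitney)."""
    pts = roc_points(scores, labels)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def youden_cutpoint(scores, labels) -> tuple[float, float]:
    """Cut-point maximising J = Se + Sp − 1 over the distinct scores.

    Ties in J break toward the larger cut-point (higher specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_class(labels)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    candidates = np.unique(scores)
    se = 1.0 - np.searchsorted(pos, candidates, side="left") / pos.size
    sp = np.searchsorted(neg, candidates, side="left") / neg.size
    j = se + sp - 1.0
    best = j.max()
    cut = candidates[j >= best - 1e-12].max()
    return float(cut), float(best)


@dataclass(frozen=True)
class ProportionEstimate:
    x: int
    n: int
    p: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError("need 0 <= x <= n")
        if not self.lo <= self.p <= self.hi:
            raise ValueError("interval must bracket the point estimate")


def crude_prevalence(
    x: int, n: int, conf_level: float = 0.95
) -> ProportionEstimate:
    """Proportion with a logit-scale CI.

    For ``0 < x < n`` the interval is the back-transformed
    ``logit(p) ± z * sqrt(1/x + 1/(n − x))``; at the boundaries the logit
    interval is undefined and the exact Clopper–Pearson interval is used
    instead.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    p = x / n
    if x == 0 or x == n:
        lo, hi = clopper_pearson(x, n, conf_level)
    else:
        z = float(stats.norm.ppf(1 - (1 - conf_level) / 2))
        logit = np.log(p / (1 - p))
        half = z * np.sqrt(1.0 / x + 1.0 / (n - x))
        lo = float(1.0 / (1.0 + np.exp(-(logit - half))))
        hi = float(1.0 / (1.0 + np.exp(-(logit + half))))
    return ProportionEstimate(x=x, n=n, p=p, lo=lo, hi=hi)


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def evaluate_model(
    records: Sequence[PresentationRecord],
    model: ScoringModel,
    conf_level: float = 0.95,
) -> dict:
    """Full accuracy report of one scorecard against labelled records.

    Returns confusion counts, Se/Sp with exact CIs, AUC of the raw score,
    and the Youden cut-point — the quantities a validation split reports.
    """
    labels = np.array([r.labels[model.group] for r in records], dtype=int)
    scores = score_many(records, model)
    preds = (scores >= model.threshold).astype(int)
    counts = confusion_from_predictions(labels, preds)
    se, sp = sens_spec(counts, conf_level)
    _, auc = roc_auc(scores, labels)
    cut, j = youden_cutpoint(scores, labels)
    return {
        "group": model.group,
        "threshold": model.threshold,
        "counts": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
        "se": {"point": se.point, "lo": se.lo, "hi": se.hi},
        "sp": {"point": sp.point, "lo": sp.lo, "hi": sp.hi},
        "auc": auc,
        "youden_cutpoint": cut,
        "youden_j": j,
    }
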