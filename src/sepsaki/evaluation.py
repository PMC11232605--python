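"""Model evaluation: confusion metrics, AUC and decision-curve analysis.

The decision curve plots, against the threshold probability p_t at which
a clinician would act, the *net benefit*

    NB(p_t) = TP(p_t)/n − FP(p_t)/n · p_t/(1 − p_t)

of acting on model predictions (predicted positive iff risk ≥ p_t),
alongside two reference policies: treat-all, whose net benefit is
π − (1 − π)·p_t/(1 − p_t) with π the outcome prevalence (a descending
line crossing zero at p_t = π), and treat-none, identically zero.  The
model is clinically useful over the threshold range where its curve
exceeds both references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import MetricUndefinedError, ValidationError

__all__ = ["ScoredCohort", "DecisionCurve", "confusion_metrics", "auc",
           "decision_curve", "benefit_range", "plot_decision_curve"]

DEFAULT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 10)


@dataclass(frozen=True)
class ScoredCohort:
    """Per-patient risk probabilities with binary outcome labels."""
    probabilities: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probabilities, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if probs.shape != labels.shape or probs.ndim != 1:
            raise ValidationError(
                "probabilities and labels must be equal-length vectors")
        if len(probs) == 0:
            raise ValidationError("cohort is empty")
        if probs.min() < 0 or probs.max() > 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValidationError("labels must be binary 0/1")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


@dataclass(frozen=True)
class DecisionCurve:
    """Net benefit of the model and of the treat-all / treat-none
    references over a threshold grid."""
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError("threshold grid must strictly increase")
        if t.min() <= 0 or t.max() >= 1:
            raise ValidationError("thresholds must lie strictly in (0, 1)")


def confusion_metrics(scored: ScoredCohort,
                      cutoff: float = 0.5) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at `cutoff`; predicted
    positive iff probability >= cutoff."""
    pred = scored.probabilities >= cutoff
    y = scored.labels.astype(bool)
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    if tp + fn == 0:
        raise MetricUndefinedError(
            "sensitivity undefined: no positive labels in cohort")
    if tn + fp == 0:
        raise MetricUndefinedError(
            "specificity undefined: no negative labels in cohort")
    return (tp / (tp + fn), tn / (tn + fp), (tp + tn) / scored.n)


def auc(scored: ScoredCohort) -> float:
    """Rank-based (Mann–Whitney) AUC; ties between a positive and a
    negative count one half."""
    if scored.labels.min() == scored.labels.max():
        raise MetricUndefinedError(
            "AUC undefined: only one class present")
    return float(roc_auc_score(scored.labels, scored.probabilities))


def decision_curve(scored: ScoredCohort,
                   grid: Optional[np.ndarray] = None) -> DecisionCurve:
    """Net-benefit curves over `grid` (default 0.01..0.99 step 0.01)."""
    t = DEFAULT_GRID.copy() if grid is None else np.asarray(grid,
                                                            dtype=float)
    if np.any(t >= 1.0) or np.any(t <= 0.0):
        raise ValidationError("thresholds must lie strictly in (0, 1)")
    odds = t / (1.0 - t)
    n = scored.n
    pi = scored.prevalence
    nb_model = np.empty_like(t)
    for i, p_t in enumerate(t):
        pred = scored.probabilities >= p_t
        tp = np.sum(pred & (scored.labels == 1))
        fp = np.sum(pred & (scored.labels == 0))
        nb_model[i] = tp / n - (fp / n) * odds[i]
    nb_all = pi - (1.0 - pi) * odds
    return DecisionCurve(thresholds=t, nb_model=nb_model, nb_all=nb_all,
                         nb_none=np.zeros_like(t))


def benefit_range(curve: DecisionCurve) -> Optional[tuple[float, float]]:
    """Maximal contiguous grid interval where the model's net benefit
    strictly exceeds both references; None when the model never wins."""
    wins = (curve.nb_model > curve.nb_all) & (curve.nb_model
                                              > curve.nb_none)
    if not wins.any():
        return None
    best_len, best = 0, None
    start = None
    padded = np.concatenate([wins, [False]])
    for i, w in enumerate(padded):
        if w and start is None:
            start = i
        elif not w and start is not None:
            if i - start > best_len:
                best_len, best = i - start, (start, i - 1)
            start = None
    lo, hi = best
    return (float(curve.thresholds[lo]), float(curve.thresholds[hi]))


def plot_decision_curve(curve: DecisionCurve, ax=None, title=None):
    """Plot the three net-benefit lines (model, treat-all, treat-none)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.thresholds, curve.nb_model, label="model", lw=2)
    ax.plot(curve.thresholds, curve.nb_all, label="ALL", ls="--")
    ax.plot(curve.thresholds, curve.nb_none, label="None", ls=":")
    ax.set_xlabel("threshold probability $p_t$")
    ax.set_ylabel("net benefit")
    lo = min(curve.nb_all.min(), -0.05)
    ax.set_ylim(max(lo, -0.25), None)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
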