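"""Predictive-performance measures for per-residue catalytic scores.

Per family: the ROC AUC (Mann-Whitney formulation, ties count 1/2), the
high-specificity partial AUC over the specificity range 1 to 0.9 (AUC01),
and the sensitivity achievable at fixed specificity thresholds. Catalytic
residues are the positive class; every other scored residue is negative.

AUC01 note: the partial area over false-positive rate in [0, 0.1] is
divided by its maximum 0.1 by default, so a perfect predictor scores 1.0
and a random one 0.05. ``normalize=False`` returns the raw partial area.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

SPECIFICITY_LEVELS = (0.99, 0.95, 0.90, 0.85)


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if labels.all() or not labels.any():
        raise ValueError("undefined AUC: need at least one positive and one negative")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney; tied scores count 1/2)."""
    scores, labels = _validate(scores, labels)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC curve as (false-positive rate, sensitivity) pairs."""
    scores, labels = _validate(scores, labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc01(scores, labels, normalize: bool = True) -> float:
    """Partial AUC over false-positive rate in [0, 0.1].

    Trapezoid over the empirical step curve with linear interpolation at
    FPR = 0.1; divided by 0.1 when ``normalize`` so perfect = 1.0 and
    random = 0.05.
    """
    pts = roc_points(scores, labels)
    fpr, tpr = pts[:, 0], pts[:, 1]
    cut = 0.1
    keep = fpr <= cut
    grid_f = np.append(fpr[keep], cut)
    grid_t = np.append(tpr[keep], np.interp(cut, fpr, tpr))
    area = float(np.trapezoid(grid_t, grid_f))
    return area / cut if normalize else area


def sensitivity_at_specificity(scores, labels, specificity: float) -> tuple[float, float]:
    """Best sensitivity among cutoffs with specificity >= the requested level.

    Returns ``(sensitivity, score_cutoff)`` — the cutoff achieving that
    sensitivity (residues scoring >= cutoff are called catalytic).
    """
    if not 0.0 < specificity <= 1.0:
        raise ValueError("specificity must lie in (0, 1]")
    scores, labels = _validate(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    feasible = fpr <= (1.0 - specificity) + 1e-12
    if not feasible.any():
        return 0.0, float("inf")
    best = np.argmax(np.where(feasible, tpr, -1.0))
    return float(tpr[best]), float(thr[best])


@dataclasses.dataclass
class EvaluationResult:
    """Per-family predictive performance summary."""

    auc: float
    auc01: float
    roc_points: np.ndarray
    sensitivities_at: dict[float, float]
    thresholds_at: dict[float, float]
    n_positive: int
    n_negative: int


def evaluate(scores, labels) -> EvaluationResult:
    """AUC, AUC01, ROC curve and sensitivities at the standard levels."""
    scores, labels = _validate(scores, labels)
    sens, thrs = {}, {}
    for level in SPECIFICITY_LEVELS:
        s, t = sensitivity_at_specificity(scores, labels, level)
        sens[level], thrs[level] = s, t
    return EvaluationResult(
        auc=roc_auc(scores, labels),
        auc01=auc01(scores, labels),
        roc_points=roc_points(scores, labels),
        sensitivities_at=sens,
        thresholds_at=thrs,
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )


def auc_rows(score_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized Mann-Whitney AUC of each row of ``score_matrix``.

    Used by the grid search, where thousands of candidate weightings are
    ranked against the same labels at once.
    """
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("undefined AUC: need at least one positive and one negative")
    ranks = rankdata(score_matrix, axis=1)
    return (ranks[:, labels].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
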