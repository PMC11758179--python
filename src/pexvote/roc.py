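"""Empirical ROC analysis: AUC, DeLong confidence intervals, top-left
threshold selection, and confusion metrics.

Conventions, used consistently across the package:

* The positive class in all response work is the non-responder (SD/PD/NE).
* Under ``higher_is_positive`` a positive call is *strictly above* the
  threshold; under ``lower_is_positive`` strictly below. Equality never
  produces a positive call.
* Candidate thresholds are midpoints between consecutive distinct observed
  scores, with -inf/+inf sentinels. For vote scores with levels k/m this
  reproduces thresholds such as 9/14 = 0.643 (between 4/7 and 5/7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

HIGHER_IS_POSITIVE = "higher_is_positive"
LOWER_IS_POSITIVE = "lower_is_positive"
ORIENTATIONS = (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived rates at a fixed decision threshold.

    ``ppv``/``npv`` are ``None`` when their denominator is empty, or are
    prevalence-adjusted post-test probabilities when computed through
    Bayes' rule with an externally supplied prevalence.
    """

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class RocResult:
    """Full empirical ROC curve for one score vector."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    orientation: str
    positive_class_size: int
    negative_class_size: int
    scores: np.ndarray
    labels: np.ndarray


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-D vectors of equal length")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    if y.all() or (~y).all():
        raise ValidationError("both classes must be non-empty")
    return s, y


def _check_orientation(orientation: str) -> None:
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {ORIENTATIONS}")


def auc_mann_whitney(scores, labels, orientation: str = HIGHER_IS_POSITIVE) -> float:
    """Tie-corrected AUC: P(pos > neg) + 0.5 P(pos == neg) under the
    stated orientation, computed via midranks."""
    _check_orientation(orientation)
    s, y = _as_arrays(scores, labels)
    if orientation == LOWER_IS_POSITIVE:
        s = -s
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (per-observation placement values)."""
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    ranks_all = stats.rankdata(s)
    ranks_pos = stats.rankdata(s[y])
    ranks_neg = stats.rankdata(s[~y])
    v10 = (ranks_all[y] - ranks_pos) / n_neg          # fraction of negs below each pos
    v01 = 1.0 - (ranks_all[~y] - ranks_neg) / n_pos   # fraction of poss above each neg
    auc = float(v10.mean())
    return v10, v01, auc


def delong_ci(
    scores, labels, alpha: float = 0.05, orientation: str = HIGHER_IS_POSITIVE
) -> tuple[float, float]:
    """Normal-approximation 95% (by default) CI for the AUC using DeLong's
    nonparametric variance, clipped to [0, 1]."""
    _check_orientation(orientation)
    s, y = _as_arrays(scores, labels)
    if orientation == LOWER_IS_POSITIVE:
        s = -s
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError("DeLong CI requires at least 2 observations per class")
    v10, v01, auc = _placements(s, y)
    var = v10.var(ddof=1) / n_pos + v01.var(ddof=1) / n_neg
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return (float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0)))


def roc_curve(scores, labels, orientation: str = HIGHER_IS_POSITIVE) -> RocResult:
    """Empirical ROC over midpoint thresholds (with ∓inf sentinels)."""
    _check_orientation(orientation)
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    if orientation == HIGHER_IS_POSITIVE:
        # positive call: score strictly above threshold
        pos_called = n_pos - np.searchsorted(pos_sorted, thresholds, side="right")
        neg_called = n_neg - np.searchsorted(neg_sorted, thresholds, side="right")
    else:
        # positive call: score strictly below threshold
        pos_called = np.searchsorted(pos_sorted, thresholds, side="left")
        neg_called = np.searchsorted(neg_sorted, thresholds, side="left")
    sens = pos_called / n_pos
    spec = 1.0 - neg_called / n_neg

    auc = auc_mann_whitney(s, y, orientation)
    if n_pos >= 2 and n_neg >= 2:
        ci = delong_ci(s, y, orientation=orientation)
    else:
        ci = (auc, auc)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=ci,
        orientation=orientation,
        positive_class_size=n_pos,
        negative_class_size=n_neg,
        scores=s,
        labels=y,
    )


def confusion_at(
    scores,
    labels,
    threshold: float,
    orientation: str = HIGHER_IS_POSITIVE,
    prevalence_override: float | None = None,
) -> ConfusionMetrics:
    """Confusion metrics at a fixed threshold.

    ``ppv``/``npv`` come from the observed counts, or — when
    ``prevalence_override`` (the pre-test probability of the positive
    class) is given — from Bayes' rule:
    ``ppv = sens*pi / (sens*pi + (1-spec)(1-pi))`` and
    ``npv = spec*(1-pi) / (spec*(1-pi) + (1-sens)*pi)``.
    """
    _check_orientation(orientation)
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    s, y = _as_arrays(scores, labels)
    if orientation == HIGHER_IS_POSITIVE:
        called = s > threshold
    else:
        called = s < threshold
    tp = int((called & y).sum())
    fp = int((called & ~y).sum())
    fn = int((~called & y).sum())
    tn = int((~called & ~y).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if prevalence_override is not None:
        pi = float(prevalence_override)
        if not 0.0 < pi < 1.0:
            raise ValidationError("prevalence_override must be in (0, 1)")
        denom_p = sens * pi + (1 - spec) * (1 - pi)
        denom_n = spec * (1 - pi) + (1 - sens) * pi
        ppv = sens * pi / denom_p if denom_p > 0 else None
        npv = spec * (1 - pi) / denom_n if denom_n > 0 else None
    else:
        ppv = tp / (tp + fp) if (tp + fp) > 0 else None
        npv = tn / (tn + fn) if (tn + fn) > 0 else None
    return ConfusionMetrics(
        threshold=float(threshold), sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, tp=tp, fp=fp, tn=tn, fn=fn,
    )


def select_threshold_topleft(roc: RocResult) -> ConfusionMetrics:
    """Threshold at the ROC point nearest the top-left corner.

    Minimizes ``(1-sens)^2 + (1-spec)^2``; ties are broken toward higher
    specificity. The reported threshold is the midpoint of the two
    adjacent distinct observed scores bracketing the chosen cut.
    """
    d2 = (1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2
    best = d2.min()
    candidates = np.flatnonzero(d2 <= best + 1e-12)
    idx = candidates[np.argmax(roc.specificity[candidates])]
    threshold = float(roc.thresholds[idx])
    if not np.isfinite(threshold):
        # degenerate curve (e.g. constant scores): report sentinel rates
        # without counts-by-comparison, keeping sens/spec from the curve.
        return ConfusionMetrics(
            threshold=threshold,
            sensitivity=float(roc.sensitivity[idx]),
            specificity=float(roc.specificity[idx]),
            ppv=None, npv=None,
            tp=0, fp=0, tn=0, fn=0,
        )
    return confusion_at(roc.scores, roc.labels, threshold, roc.orientation)
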