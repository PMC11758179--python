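"""Directional threshold-vote marker combinations.

Each marker rule assigns one point when a patient's value falls on the
non-responder side of the marker's threshold: strictly *above* for an
unfavorable marker (elevated in non-responders; includes the NLR) and
strictly *below* for a favorable marker. Equality never votes. A
combination's score is the mean of its members' votes, so an m-marker
score lives on {0, 1/m, ..., 1}; 0 means no member predicted
non-response, 1 means all did.

The search enumerates every marker subset in a size range, scores every
eligible patient (patients missing any member measurement are excluded,
never imputed), and ranks combinations by the AUC for discriminating
non-responders, with DeLong CIs and top-left-threshold confusion metrics.
Per-marker thresholds are fit once on the training cohort and reused
unchanged inside every combination and in any later frozen application.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    FAVORABLE,
    NLR_MARKER,
    UNFAVORABLE,
    AnalysisConfig,
)
from .errors import MissingMarkerError, ValidationError
from .io import ClinicalTable
from .normalize import delta_ct
from .roc import (
    HIGHER_IS_POSITIVE,
    LOWER_IS_POSITIVE,
    ConfusionMetrics,
    roc_curve,
    select_threshold_topleft,
)

SCORE_HIGH = "score_high"
SCORE_LOW = "score_low"


@dataclass(frozen=True)
class MarkerRule:
    """A marker with a direction and a frozen decision threshold."""

    marker: str
    direction: str
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in (UNFAVORABLE, FAVORABLE):
            raise ValidationError(f"bad direction {self.direction!r}")
        if not np.isfinite(self.threshold):
            raise ValidationError(f"rule {self.marker!r}: threshold must be finite")


def vote(rule: MarkerRule, value: float) -> int:
    """One point iff the value falls strictly on the non-responder side."""
    if value is None or not np.isfinite(value):
        raise MissingMarkerError(f"missing value for marker {rule.marker!r}")
    if rule.direction == UNFAVORABLE:
        return int(value > rule.threshold)
    return int(value < rule.threshold)


def votes(rule: MarkerRule, values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`vote`; NaN inputs propagate as NaN (missing)."""
    v = np.asarray(values, dtype=float)
    if rule.direction == UNFAVORABLE:
        out = (v > rule.threshold).astype(float)
    else:
        out = (v < rule.threshold).astype(float)
    out[np.isnan(v)] = np.nan
    return out


def _rule_sort_key(name: str) -> tuple[bool, str]:
    return (name == NLR_MARKER, name)  # genes alphabetical, NLR last


@dataclass(frozen=True)
class Combination:
    """An ordered set of unique marker rules."""

    rules: tuple[MarkerRule, ...]

    def __post_init__(self) -> None:
        if len(self.rules) < 1:
            raise ValidationError("a combination needs at least one rule")
        names = [r.marker for r in self.rules]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate markers in combination: {names}")

    @property
    def m(self) -> int:
        return len(self.rules)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(r.marker for r in self.rules)


def combination_score(comb: Combination, patient_values) -> float:
    """Mean of member votes for one patient (mapping marker -> value).

    Raises :class:`MissingMarkerError` if any member marker is missing;
    the caller excludes such patients rather than scoring them 0.
    """
    total = 0
    for rule in comb.rules:
        if rule.marker not in patient_values:
            raise MissingMarkerError(f"missing value for marker {rule.marker!r}")
        total += vote(rule, patient_values[rule.marker])
    return total / comb.m


def enumerate_combinations(
    rules: list[MarkerRule], size_min: int = 2, size_max: int | None = None
):
    """Yield every subset of ``rules`` with size in [size_min, size_max],
    each exactly once, ordered by size then lexicographically by marker
    names (genes alphabetical, NLR last)."""
    if size_max is None:
        size_max = len(rules)
    if not 1 <= size_min <= size_max <= len(rules):
        raise ValidationError(
            f"need 1 <= size_min <= size_max <= {len(rules)}, "
            f"got [{size_min}, {size_max}]"
        )
    ordered = sorted(rules, key=lambda r: _rule_sort_key(r.marker))
    for size in range(size_min, size_max + 1):
        yield from (Combination(rules=c) for c in itertools.combinations(ordered, size))


@dataclass
class CombinationResult:
    combination: Combination
    auc: float
    auc_ci: tuple[float, float]
    metrics: ConfusionMetrics
    rank: int
    n_used: int
    n_excluded: int


def marker_matrix(table: ClinicalTable, config: AnalysisConfig) -> pd.DataFrame:
    """Patients-by-markers value matrix on the scales the rules use:
    -dCt for genes, the raw ratio for NLR."""
    mat = delta_ct(table, config.reference_gene)
    missing = [g for g in config.marker_genes if g not in mat.columns]
    if missing:
        raise ValidationError(f"markers without Ct columns: {missing}")
    mat = mat[list(config.marker_genes)]
    if config.nlr_included:
        mat = mat.assign(
            **{NLR_MARKER: pd.Series(
                table.frame["nlr"].to_numpy(), index=table.frame["patient_id"].to_numpy()
            )}
        )
    return mat


def fit_marker_rules(table: ClinicalTable, config: AnalysisConfig) -> list[MarkerRule]:
    """Fit one top-left ROC threshold per marker on the full cohort.

    Orientation follows the configured direction: unfavorable markers use
    higher-is-positive, favorable lower-is-positive, positive class =
    non-responder.
    """
    values = marker_matrix(table, config)
    labels = table.nonresponder_labels()
    rules = []
    directions = dict(config.marker_directions)
    if config.nlr_included:
        directions[NLR_MARKER] = UNFAVORABLE
    for marker in values.columns:
        direction = directions[marker]
        orientation = HIGHER_IS_POSITIVE if direction == UNFAVORABLE else LOWER_IS_POSITIVE
        v = values[marker].to_numpy()
        ok = ~np.isnan(v)
        roc = roc_curve(v[ok], labels[ok], orientation)
        metrics = select_threshold_topleft(roc)
        rules.append(MarkerRule(marker=marker, direction=direction,
                                threshold=metrics.threshold))
    return rules


def _score_matrix(comb: Combination, values: pd.DataFrame) -> pd.Series:
    """Vote-average score per patient; NaN where any member is missing."""
    cols = np.column_stack([votes(r, values[r.marker].to_numpy()) for r in comb.rules])
    return pd.Series(cols.mean(axis=1), index=values.index)


def rank_combinations(
    table: ClinicalTable, rules: list[MarkerRule], config: AnalysisConfig
) -> list[CombinationResult]:
    """Exhaustively score and AUC-rank marker subsets.

    Sorting: AUC desc, then fewer markers, then lexicographic marker
    names. Returns the configured top-k. Combinations whose eligible
    patients no longer span both classes are dropped (recorded by the
    pipeline manifest, not silently lost: the count of enumerated vs
    returned combinations is exposed there).
    """
    values = marker_matrix(table, config)
    labels = pd.Series(table.nonresponder_labels(), index=values.index)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValidationError("need >=2 patients per response class")

    vote_cols = {r.marker: votes(r, values[r.marker].to_numpy()) for r in rules}
    scored: list[CombinationResult] = []
    for comb in enumerate_combinations(rules, config.combination_size_min,
                                       min(config.resolved_size_max, len(rules))):
        cols = np.column_stack([vote_cols[r.marker] for r in comb.rules])
        valid = ~np.isnan(cols).any(axis=1)
        score = cols[valid].mean(axis=1)
        lab = labels.to_numpy()[valid]
        if lab.sum() < 2 or (~lab).sum() < 2:
            continue
        roc = roc_curve(score, lab)
        metrics = select_threshold_topleft(roc)
        scored.append(CombinationResult(
            combination=comb, auc=roc.auc, auc_ci=roc.auc_ci, metrics=metrics, rank=0,
            n_used=int(valid.sum()), n_excluded=int((~valid).sum()),
        ))
    scored.sort(key=lambda r: (-r.auc, r.combination.m,
                               tuple(_rule_sort_key(n) for n in r.combination.markers)))
    top = scored[: config.top_k_combinations]
    for i, res in enumerate(top, start=1):
        res.rank = i
    return top


def apply_frozen_combination(
    comb: Combination, threshold_score: float, values: pd.DataFrame
) -> pd.Series:
    """Label patients score_high / score_low with frozen thresholds.

    ``values`` is a patients-by-markers matrix (same scales as training).
    No refitting happens here: both the per-marker thresholds inside
    ``comb`` and the score cut are taken as given. A score exactly at the
    cut is score_low, consistent with strict votes. Patients missing a
    member marker are excluded (absent from the returned series).
    """
    if not np.isfinite(threshold_score):
        raise ValidationError("threshold_score must be finite")
    missing = [r.marker for r in comb.rules if r.marker not in values.columns]
    if missing:
        raise MissingMarkerError(f"value matrix lacks markers {missing}")
    score = _score_matrix(comb, values)
    ok = score.notna()
    labels = np.where(score[ok] > threshold_score, SCORE_HIGH, SCORE_LOW)
    return pd.Series(labels, index=score.index[ok], name="signature")
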