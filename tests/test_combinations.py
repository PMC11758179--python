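"""Threshold-vote scoring, exhaustive enumeration and AUC ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pexvote import (
    AnalysisConfig,
    Combination,
    MarkerRule,
    SimulationSpec,
    apply_frozen_combination,
    auc_mann_whitney,
    combination_score,
    enumerate_combinations,
    fit_marker_rules,
    rank_combinations,
    simulate_part1_cohort,
    vote,
)
from pexvote.combinations import SCORE_HIGH, SCORE_LOW, marker_matrix
from pexvote.config import FAVORABLE, UNFAVORABLE
from pexvote.errors import MissingMarkerError, ValidationError


def _rules(n=7):
    names = [f"M{i}" for i in range(n - 1)] + ["NLR"]
    return [MarkerRule(m, UNFAVORABLE, 0.5) for m in names]


class TestVote:
    def test_equality_never_votes(self):
        assert vote(MarkerRule("HLA-E", UNFAVORABLE, 1.0), 1.0) == 0
        assert vote(MarkerRule("RABL2B", FAVORABLE, 1.0), 1.0) == 0

    def test_favorable_below_votes(self):
        assert vote(MarkerRule("RABL2B", FAVORABLE, -5.0), -6.0) == 1

    def test_unfavorable_above_votes(self):
        assert vote(MarkerRule("HLA-E", UNFAVORABLE, -5.0), -4.0) == 1

    def test_missing_value_raises(self):
        with pytest.raises(MissingMarkerError):
            vote(MarkerRule("HLA-E", UNFAVORABLE, 0.0), float("nan"))

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_negation_symmetry(self, value, threshold):
        """Negating value and threshold while flipping the direction
        leaves the vote unchanged."""
        a = vote(MarkerRule("G", UNFAVORABLE, threshold), value)
        b = vote(MarkerRule("G", FAVORABLE, -threshold), -value)
        assert a == b


class TestCombinationScore:
    def test_unanimous(self):
        comb = Combination(tuple(MarkerRule(f"G{i}", UNFAVORABLE, 0.0) for i in range(3)))
        assert combination_score(comb, {f"G{i}": 1.0 for i in range(3)}) == 1.0

    def test_five_of_seven(self):
        comb = Combination(tuple(MarkerRule(f"G{i}", UNFAVORABLE, 0.0) for i in range(7)))
        values = {f"G{i}": (1.0 if i < 5 else -1.0) for i in range(7)}
        assert combination_score(comb, values) == pytest.approx(5 / 7)

    def test_missing_member_excludes_not_zero(self):
        comb = Combination((MarkerRule("A", UNFAVORABLE, 0.0),
                            MarkerRule("B", UNFAVORABLE, 0.0)))
        with pytest.raises(MissingMarkerError):
            combination_score(comb, {"A": 1.0})

    def test_flip_one_vote_moves_score_by_one_over_m(self):
        comb = Combination(tuple(MarkerRule(f"G{i}", UNFAVORABLE, 0.0) for i in range(5)))
        base = {f"G{i}": -1.0 for i in range(5)}
        flipped = dict(base, G2=1.0)
        delta = combination_score(comb, flipped) - combination_score(comb, base)
        assert delta == pytest.approx(1 / 5)

    def test_score_invariant_under_rule_reordering(self):
        rules = tuple(MarkerRule(f"G{i}", UNFAVORABLE, float(i)) for i in range(4))
        values = {f"G{i}": float(i) + (0.5 if i % 2 else -0.5) for i in range(4)}
        scores = {combination_score(Combination(p), values)
                  for p in itertools.permutations(rules)}
        assert len(scores) == 1


class TestEnumerate:
    def test_seven_markers_counts(self):
        assert sum(1 for _ in enumerate_combinations(_rules(7), 2, 7)) == 120
        assert sum(1 for _ in enumerate_combinations(_rules(7), 1, 7)) == 127

    def test_duplicate_free(self):
        seen = {frozenset(c.markers) for c in enumerate_combinations(_rules(7), 2, 7)}
        assert len(seen) == 120

    def test_order_by_size_then_lexicographic(self):
        combos = list(enumerate_combinations(_rules(4), 1, 4))
        sizes = [c.m for c in combos]
        assert sizes == sorted(sizes)
        names = [c.markers for c in combos if c.m == 2]
        assert names == sorted(names, key=lambda t: tuple((n == "NLR", n) for n in t))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            list(enumerate_combinations(_rules(4), 3, 2))


def _brute_force_rank(values: pd.DataFrame, labels: np.ndarray, rules, k: int):
    """Independent reference: recompute every subset's AUC with plain loops."""
    results = []
    by_name = {r.marker: r for r in rules}
    names = sorted(by_name, key=lambda n: (n == "NLR", n))
    for size in range(2, len(names) + 1):
        for subset in itertools.combinations(names, size):
            scores = []
            for _, row in values.iterrows():
                pts = [vote(by_name[n], row[n]) for n in subset]
                scores.append(sum(pts) / len(pts))
            auc = auc_mann_whitney(np.array(scores), labels)
            results.append((subset, auc))
    results.sort(key=lambda t: (-t[1], len(t[0]), t[0]))
    return results[:k]


class TestRankCombinations:
    @pytest.fixture(scope="class")
    def cohort(self):
        spec = SimulationSpec(seed=42)
        table = simulate_part1_cohort(spec)
        config = AnalysisConfig(rng_seed=42)
        return table, config

    def test_topk_ranks(self, cohort):
        table, config = cohort
        rules = fit_marker_rules(table, config)
        results = rank_combinations(table, rules, config)
        assert [r.rank for r in results] == list(range(1, 11))
        aucs = [r.auc for r in results]
        assert aucs == sorted(aucs, reverse=True)

    def test_matches_bruteforce_reference(self, cohort):
        table, config = cohort
        rules = fit_marker_rules(table, config)
        results = rank_combinations(table, rules, config)
        values = marker_matrix(table, config)
        labels = table.nonresponder_labels()
        reference = _brute_force_rank(values, labels, rules,
                                      config.top_k_combinations)
        for ours, (subset, auc) in zip(results, reference):
            assert tuple(sorted(ours.combination.markers,
                                key=lambda n: (n == "NLR", n))) == subset
            assert ours.auc == pytest.approx(auc, abs=1e-12)

    def test_single_class_rejected(self, cohort):
        table, config = cohort
        rules = fit_marker_rules(table, config)
        bad = table.frame.copy()
        bad["bor"] = "PD"
        from pexvote import ClinicalTable
        with pytest.raises(ValidationError):
            rank_combinations(ClinicalTable(frame=bad, genes=table.genes),
                              rules, config)


class TestApplyFrozen:
    def _setup(self):
        comb = Combination((MarkerRule("A", UNFAVORABLE, 0.0),
                            MarkerRule("B", FAVORABLE, 0.0)))
        values = pd.DataFrame({"A": [1.0, -1.0, 1.0], "B": [-1.0, 1.0, 1.0]},
                              index=["p1", "p2", "p3"])
        return comb, values

    def test_strict_cut(self):
        comb, values = self._setup()
        # scores: p1 = 1.0, p2 = 0.0, p3 = 0.5
        labels = apply_frozen_combination(comb, 0.5, values)
        assert labels["p1"] == SCORE_HIGH
        assert labels["p3"] == SCORE_LOW  # exactly at the cut -> low

    def test_missing_member_excluded(self):
        comb, values = self._setup()
        values.loc["p2", "A"] = np.nan
        labels = apply_frozen_combination(comb, 0.5, values)
        assert "p2" not in labels.index and len(labels) == 2

    def test_training_idempotence(self):
        """Applying the frozen combination back to its training cohort
        reproduces the confusion counts recorded at selection time."""
        spec = SimulationSpec(seed=9)
        table = simulate_part1_cohort(spec)
        config = AnalysisConfig(rng_seed=9)
        rules = fit_marker_rules(table, config)
        results = rank_combinations(table, rules, config)
        best = results[0]
        values = marker_matrix(table, config)
        labels = apply_frozen_combination(best.combination,
                                          best.metrics.threshold, values)
        high = (labels == SCORE_HIGH).to_numpy()
        nonresp = table.nonresponder_labels()
        assert int((high & nonresp).sum()) == best.metrics.tp
        assert int((high & ~nonresp).sum()) == best.metrics.fp
        assert int((~high & ~nonresp).sum()) == best.metrics.tn
        assert int((~high & nonresp).sum()) == best.metrics.fn
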