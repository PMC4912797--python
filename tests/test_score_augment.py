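"""25OHD categorization, assignment enumeration, and the AUC search."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vdscore as v
from vdscore.errors import DegenerateInputError

from _oracles import brute_search


class TestCategorize:
    @pytest.mark.parametrize(
        "level,expected",
        [
            (35.0, 0), (30.0, 0),           # boundary belongs to the higher band
            (29.9, 1), (20.0, 1),
            (19.95, 2), (15.0, 2), (10.0, 2),
            (9.99, 3), (0.5, 3),
        ],
    )
    def test_band_boundaries(self, level, expected):
        assert int(v.categorize(level)) == expected

    def test_initial_assignment_worked_values(self):
        # the published initial mapping: >=30 -> 0, 10-19.9 -> 2, <10 -> 3
        a = v.INITIAL_ASSIGNMENT
        assert a.sub_score(v.categorize(30.0)) == 0
        assert a.sub_score(v.categorize(15.0)) == 2
        assert a.sub_score(v.categorize(9.99)) == 3

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.nan, math.inf])
    def test_invalid_levels_rejected(self, bad):
        with pytest.raises(DegenerateInputError):
            v.categorize(bad)

    def test_vectorized_matches_scalar(self, rng):
        levels = rng.uniform(0.5, 45.0, size=200)
        cats = v.categorize_levels(levels)
        assert all(int(v.categorize(x)) == c for x, c in zip(levels, cats))


class TestEnumerateAssignments:
    def test_default_space_has_84_assignments(self):
        space = v.enumerate_assignments()
        assert len(space) == 84  # non-decreasing triples over {0..6}: C(9,3)
        assert v.INITIAL_ASSIGNMENT in space
        assert v.COLLAPSED_ASSIGNMENT in space
        assert v.ScoreAssignment((0, 0, 0, 0)) in space

    def test_counts_match_combinatorics(self):
        assert len(v.enumerate_assignments(anchor_top_zero=False)) == 210  # C(10,4)
        assert len(v.enumerate_assignments(monotone=False)) == 7**3
        assert len(v.enumerate_assignments(anchor_top_zero=False, monotone=False)) == 7**4
        assert v.enumerate_assignments(max_sub=0) == [v.ScoreAssignment((0, 0, 0, 0))]

    def test_brute_force_count_of_monotone_anchored_tuples(self):
        brute = [
            (0, a, b, c)
            for a in range(7) for b in range(7) for c in range(7)
            if a <= b <= c
        ]
        space = [s.sub_scores for s in v.enumerate_assignments()]
        assert space == sorted(brute)

    def test_deterministic_lexicographic_order(self):
        space = v.enumerate_assignments()
        assert space == v.enumerate_assignments()
        assert [s.sub_scores for s in space] == sorted(s.sub_scores for s in space)


class TestAugment:
    def test_published_addition_rule(self):
        assert v.augment(4, 15.0, v.INITIAL_ASSIGNMENT) == 6
        assert v.augment(14, 35.0, v.INITIAL_ASSIGNMENT) == 14
        assert v.augment(0, 5.0, v.INITIAL_ASSIGNMENT) == 3

    def test_negative_base_rejected(self):
        with pytest.raises(ValueError):
            v.augment(-1, 15.0, v.INITIAL_ASSIGNMENT)

    @given(
        base=st.integers(0, 70),
        level=st.floats(0.5, 60.0, allow_nan=False),
        bump=st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_base_and_nonincreasing_in_level(self, base, level, bump):
        a = v.INITIAL_ASSIGNMENT
        assert v.augment(base + bump, level, a) >= v.augment(base, level, a)
        assert v.augment(base, level + float(bump), a) <= v.augment(base, level, a)

    def test_vectorized_matches_scalar(self, rng):
        base = rng.integers(0, 20, size=50)
        levels = rng.uniform(0.5, 45.0, size=50)
        out = v.augment_scores(base, levels, v.COLLAPSED_ASSIGNMENT)
        assert list(out) == [
            v.augment(int(b), float(x), v.COLLAPSED_ASSIGNMENT)
            for b, x in zip(base, levels)
        ]


class TestSearchBest:
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_independent_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        labels = np.zeros(n, dtype=int)
        labels[: n // 3] = 1
        rng.shuffle(labels)
        base = rng.integers(0, 10, size=n)
        levels = rng.uniform(0.5, 40.0, size=n)
        space = v.enumerate_assignments(max_sub=3)  # 20 assignments: fast oracle
        result = v.search_best(base, levels, labels, search_space=space)
        cats = [int(v.categorize(x)) for x in levels]
        assert result.best_assignment == brute_search(base, cats, labels, space)
        assert result.n_evaluated == len(space)

    def test_all_zero_wins_when_base_separates_perfectly(self, rng):
        n = 40
        labels = np.repeat([0, 1], n // 2)
        base = np.where(labels == 1, 100, 0) + rng.integers(0, 5, size=n)
        levels = rng.uniform(0.5, 40.0, size=n)
        result = v.search_best(base, levels, labels)
        assert result.best_assignment == v.ScoreAssignment((0, 0, 0, 0))
        assert result.best_auc.auc == 1.0

    def test_best_never_below_unaugmented_auc(self, rng):
        labels = (rng.random(60) < 0.4).astype(int)
        base = rng.integers(0, 15, size=60)
        levels = rng.uniform(0.5, 40.0, size=60)
        result = v.search_best(base, levels, labels)
        assert result.best_auc.auc >= v.auc(base.astype(float), labels).auc - 1e-12

    def test_leaderboard_sorted_and_headed_by_winner(self, rng):
        labels = (rng.random(50) < 0.3).astype(int)
        base = rng.integers(0, 10, size=50)
        levels = rng.uniform(0.5, 40.0, size=50)
        result = v.search_best(base, levels, labels)
        aucs = [a for _, a in result.leaderboard]
        assert aucs == sorted(aucs, reverse=True)
        assert result.leaderboard[0][0] == result.best_assignment

    def test_empty_search_space_rejected(self, rng):
        labels = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            v.search_best([1, 2, 3, 4], [5.0, 15.0, 25.0, 35.0], labels, search_space=[])

    def test_strong_category_effect_is_detected(self):
        # when deficiency drives mortality independently of the base score,
        # the winning assignment should be non-zero in nearly every cohort
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n = 200
            levels = rng.uniform(0.5, 40.0, size=n)
            cats = v.categorize_levels(levels)
            p = 1.0 / (1.0 + np.exp(-(-2.5 + 1.2 * cats)))
            labels = (rng.random(n) < p).astype(int)
            if labels.sum() in (0, n):
                continue
            base = rng.integers(0, 10, size=n)  # uninformative base index
            result = v.search_best(base, levels, labels)
            hits += result.best_assignment != v.ScoreAssignment((0, 0, 0, 0))
        assert hits >= 0.95 * n_runs

    def test_search_is_deterministic(self, rng):
        labels = (rng.random(80) < 0.3).astype(int)
        base = rng.integers(0, 12, size=80)
        levels = rng.uniform(0.5, 40.0, size=80)
        r1 = v.search_best(base, levels, labels)
        r2 = v.search_best(base, levels, labels)
        assert r1.best_assignment == r2.best_assignment
        assert r1.leaderboard == r2.leaderboard
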