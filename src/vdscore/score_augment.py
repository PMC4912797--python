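"""Augmenting a base risk index with 25OHD-category sub-scores.

Plasma 25OHD is categorized into the nationally accepted bands
>=30, 20-29.9, 10-19.9 and <10 ng/mL (boundaries belong to the higher band,
so the bands are the half-open intervals [30, inf), [20, 30), [10, 20),
(0, 10)). Each band receives a small integer sub-score which is added to the
base index (DCCI or APACHE II); the "serial" search space is the set of
non-decreasing integer assignments from the sufficient band toward
deficiency, each sub-score bounded by 6, with the >=30 band anchored at 0.
``search_best`` exhaustively evaluates a search space and returns the
assignment maximizing the in-sample AUC for the outcome, breaking ties toward
parsimony (smaller sub-score sum, then lexicographic order) so the all-zero
assignment wins when augmentation adds nothing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateInputError
from .roc_delong import AUCResult, auc, _validate


class VitDCategory(IntEnum):
    """Ordinal 25OHD band, from sufficiency (0) toward deficiency (3)."""

    SUFFICIENT = 0      # >= 30 ng/mL
    INSUFFICIENT = 1    # 20 - 29.9 ng/mL
    LOW = 2             # 10 - 19.9 ng/mL
    DEFICIENT = 3       # < 10 ng/mL


_BAND_EDGES = np.array([10.0, 20.0, 30.0])


@dataclass(frozen=True)
class ScoreAssignment:
    """Integer sub-scores per 25OHD band, in band order (>=30 first)."""

    sub_scores: tuple[int, int, int, int]

    def __post_init__(self):
        if len(self.sub_scores) != 4:
            raise ValueError("an assignment has exactly four sub-scores")
        if any((not float(s).is_integer()) or s < 0 for s in self.sub_scores):
            raise ValueError(f"sub-scores must be non-negative integers, got {self.sub_scores}")
        object.__setattr__(self, "sub_scores", tuple(int(s) for s in self.sub_scores))

    @property
    def is_monotone(self) -> bool:
        s = self.sub_scores
        return s[0] <= s[1] <= s[2] <= s[3]

    @property
    def is_anchored(self) -> bool:
        return self.sub_scores[0] == 0

    @property
    def total(self) -> int:
        return sum(self.sub_scores)

    def sub_score(self, category: VitDCategory) -> int:
        return self.sub_scores[int(category)]


#: The published initial assignment: 0 / 1 / 2 / 3 toward deficiency.
INITIAL_ASSIGNMENT = ScoreAssignment((0, 1, 2, 3))
#: The published collapsed variant merging the two middle bands.
COLLAPSED_ASSIGNMENT = ScoreAssignment((0, 1, 1, 3))


def categorize(level: float) -> VitDCategory:
    """Map a 25OHD level (ng/mL) to its threshold band.

    Rejects non-positive or non-finite levels.
    """
    if not math.isfinite(level) or level <= 0:
        raise DegenerateInputError(f"25OHD level must be positive and finite, got {level}")
    if level >= 30:
        return VitDCategory.SUFFICIENT
    if level >= 20:
        return VitDCategory.INSUFFICIENT
    if level >= 10:
        return VitDCategory.LOW
    return VitDCategory.DEFICIENT


def categorize_levels(levels) -> np.ndarray:
    """Vectorized :func:`categorize`; returns ordinal band indices 0..3."""
    levels = np.asarray(levels, dtype=float)
    if not np.all(np.isfinite(levels)) or np.any(levels <= 0):
        raise DegenerateInputError("25OHD levels must be positive and finite")
    return (3 - np.digitize(levels, _BAND_EDGES)).astype(np.int64)


def enumerate_assignments(
    max_sub: int = 6,
    anchor_top_zero: bool = True,
    monotone: bool = True,
) -> list[ScoreAssignment]:
    """All assignments with sub-scores in [0, max_sub], lexicographic order.

    With the defaults (anchored, monotone) the space is the non-decreasing
    triples over {0..max_sub} prefixed by 0; it always contains the all-zero
    assignment.
    """
    if max_sub < 0:
        raise ValueError(f"max_sub must be non-negative, got {max_sub}")
    values = range(max_sub + 1)
    width = 3 if anchor_top_zero else 4
    if monotone:
        tuples = itertools.combinations_with_replacement(values, width)
    else:
        tuples = itertools.product(values, repeat=width)
    if anchor_top_zero:
        return [ScoreAssignment((0, *t)) for t in tuples]
    return [ScoreAssignment(tuple(t)) for t in tuples]


def augment(base_score: int, level: float, assignment: ScoreAssignment) -> int:
    """Base index plus the sub-score of the patient's 25OHD band."""
    if base_score < 0:
        raise ValueError(f"base_score must be non-negative, got {base_score}")
    return int(base_score) + assignment.sub_score(categorize(level))


def augment_scores(base_scores, levels, assignment: ScoreAssignment) -> np.ndarray:
    """Vectorized :func:`augment` over aligned arrays."""
    base = np.asarray(base_scores)
    if np.any(base < 0):
        raise ValueError("base scores must be non-negative")
    cats = categorize_levels(levels)
    subs = np.asarray(assignment.sub_scores)
    return base + subs[cats]


@dataclass(frozen=True)
class AugmentationSearchResult:
    best_assignment: ScoreAssignment
    best_auc: AUCResult
    n_evaluated: int
    leaderboard: list  # (ScoreAssignment, auc) sorted best-first


def search_best(
    base_scores,
    levels,
    labels,
    search_space: list[ScoreAssignment] | None = None,
    max_sub: int = 6,
    anchor_top_zero: bool = True,
    monotone: bool = True,
) -> AugmentationSearchResult:
    """Exhaustive AUC maximization over a sub-score assignment space.

    Deterministic: every assignment is evaluated, the winner is the maximal
    AUC with ties broken by smaller sub-score sum then lexicographic order.
    """
    if search_space is None:
        search_space = enumerate_assignments(max_sub, anchor_top_zero, monotone)
    if not search_space:
        raise ValueError("search space must not be empty")

    base = np.asarray(base_scores, dtype=float)
    cats = categorize_levels(levels)
    _, labels = _validate(np.zeros_like(base), labels)
    m = int(labels.sum())
    n_neg = labels.size - m
    pos = labels == 1

    # Mann-Whitney AUC via the rank-sum: the numerator is an exact
    # half-integer, so exactly tied assignments compare equal and the
    # deterministic tie-break (smaller sum, then lexicographic) applies.
    scored = []
    for assignment in search_space:
        subs = np.asarray(assignment.sub_scores, dtype=float)
        ranks = rankdata(base + subs[cats])
        u = float(ranks[pos].sum()) - m * (m + 1) / 2.0
        scored.append((assignment, u / (m * n_neg)))

    scored.sort(key=lambda item: (-item[1], item[0].total, item[0].sub_scores))
    best, _ = scored[0]
    subs = np.asarray(best.sub_scores, dtype=float)
    best_auc = auc(base + subs[cats], labels)
    return AugmentationSearchResult(
        best_assignment=best,
        best_auc=best_auc,
        n_evaluated=len(search_space),
        leaderboard=scored,
    )
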