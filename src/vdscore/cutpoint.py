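"""Optimal decision thresholds under the Youden criterion.

A cut-point is a rule "positive iff score >= cutoff". The optimum maximizes
sensitivity + specificity (the Youden index plus one) over all candidate
cutoffs — the distinct observed score values plus one sentinel above the
maximum (the all-negative rule). Ties are broken toward higher specificity,
then toward the higher cutoff, so an uninformative score yields the
all-negative rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden_sum: float


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be one-dimensional and aligned")
    if not np.all(np.isfinite(scores)):
        raise DegenerateInputError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise DegenerateInputError("labels must be 0/1")
    labels = labels.astype(np.int64)
    if labels.sum() in (0, labels.size):
        raise DegenerateInputError("both outcome classes must be present")
    return scores, labels


def confusion_at(scores, labels, cutoff: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of the rule score >= cutoff.

    Fractions are formed from exact integer 2x2 counts.
    """
    scores, labels = _validate(scores, labels)
    call_pos = scores >= cutoff
    tp = int(np.sum(call_pos & (labels == 1)))
    tn = int(np.sum(~call_pos & (labels == 0)))
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    return tp / n_pos, tn / n_neg, (tp + tn) / labels.size


def optimal_cutpoint(scores, labels) -> CutpointResult:
    """Exhaustive Youden scan over distinct scores plus an upper sentinel.

    Candidates are compared in exact integer arithmetic:
    ``sens + spec = (tp * n_neg + tn * n_pos) / (n_pos * n_neg)`` has a
    constant denominator, so the integer numerator orders candidates without
    float rounding; ties break toward higher specificity (``tn``), then the
    higher cutoff.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)

    uniq, inverse = np.unique(scores, return_inverse=True)
    pos_at = np.bincount(inverse[labels == 1], minlength=uniq.size)
    neg_at = np.bincount(inverse[labels == 0], minlength=uniq.size)
    # tp/fp for the rule score >= u at each distinct u, plus the sentinel rule
    tp = np.append(np.cumsum(pos_at[::-1])[::-1], 0)
    fp = np.append(np.cumsum(neg_at[::-1])[::-1], 0)
    tn = n_neg - fp
    candidates = np.append(uniq, np.max(scores) + 1.0)

    best_i = 0
    best_key = (-1, -1, -np.inf)
    for i in range(candidates.size):
        key = (int(tp[i]) * n_neg + int(tn[i]) * n_pos, int(tn[i]), candidates[i])
        if key > best_key:
            best_key, best_i = key, i
    i = best_i
    sens = tp[i] / n_pos
    spec = tn[i] / n_neg
    acc = (tp[i] + tn[i]) / labels.size
    return CutpointResult(float(candidates[i]), float(sens), float(spec),
                          float(acc), float(sens + spec))
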