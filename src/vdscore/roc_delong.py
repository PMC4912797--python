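"""Empirical ROC curves, AUC inference, and paired AUC equality testing.

The AUC is computed as the Mann-Whitney statistic (ties count 1/2), which
equals the trapezoidal area under the tie-grouped empirical ROC curve; the
identity is asserted internally. Standard errors and the paired equality test
use the U-statistic decomposition of the AUC into per-case placement values
(the DeLong construction for correlated ROC curves): for a positive case its
placement is the fraction of negatives it outranks, and symmetrically for
negatives. The equality test for two scores measured on the same patients
forms ``chi2 = delta^2 / var(delta)`` with the variance assembled from the
empirical covariances of paired placements, referred to chi-square with 1 df.

Convention: larger score means higher predicted mortality risk, and a patient
is called positive when ``score >= threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

from .errors import DegenerateInputError, DegenerateVarianceError

__all__ = [
    "ROCCurve",
    "AUCResult",
    "PairedAUCTest",
    "roc_curve",
    "auc",
    "delong_components",
    "delong_compare",
]


@dataclass(frozen=True)
class ROCCurve:
    """Tie-grouped empirical ROC curve.

    ``thresholds`` are the sorted distinct score values followed by a +inf
    sentinel; point ``i`` is the operating point of the rule
    "positive iff score >= thresholds[i]". The curve starts at
    (FPR 1, sens 1) and ends at (0, 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    false_positive_rate: np.ndarray
    n_pos: int
    n_neg: int

    def trapezoid_area(self) -> float:
        fpr, sens = self.false_positive_rate, self.sensitivity
        return float(np.sum((fpr[:-1] - fpr[1:]) * (sens[:-1] + sens[1:]) / 2.0))


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairedAUCTest:
    auc_a: float
    auc_b: float
    delta: float
    chi2: float
    p: float
    df: int = field(default=1)


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or labels.ndim != 1 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be one-dimensional and aligned")
    if not np.all(np.isfinite(scores)):
        raise DegenerateInputError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise DegenerateInputError("labels must be 0/1")
    labels = labels.astype(np.int64)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise DegenerateInputError("both outcome classes must be present")
    return scores, labels


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC with one point per distinct score value plus a sentinel."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)

    uniq, inverse = np.unique(scores, return_inverse=True)
    pos_at = np.bincount(inverse[labels == 1], minlength=uniq.size)
    neg_at = np.bincount(inverse[labels == 0], minlength=uniq.size)
    # counts of cases with score >= each distinct value
    tp = np.cumsum(pos_at[::-1])[::-1]
    fp = np.cumsum(neg_at[::-1])[::-1]

    thresholds = np.append(uniq, np.inf)
    sens = np.append(tp, 0) / n_pos
    fpr = np.append(fp, 0) / n_neg
    return ROCCurve(thresholds, sens, fpr, n_pos, n_neg)


def delong_components(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Placement values (per-positive, per-negative) via mid-ranks.

    The per-positive component is the fraction of negatives that the case
    outranks (ties 1/2); symmetrically for negatives. Both component sets
    average to the AUC.
    """
    scores, labels = _validate(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    r_all = rankdata(np.concatenate([pos, neg]))
    v10 = (r_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (r_all[m:] - rankdata(neg)) / m
    return v10, v01


def _auc_se(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    return float(np.sqrt(s10 / v10.size + s01 / v01.size))


def auc(scores, labels) -> AUCResult:
    """Mann-Whitney AUC with a DeLong standard error and Wald 95 % CI."""
    v10, v01 = delong_components(scores, labels)
    a = float(v10.mean())
    # internal consistency: trapezoid under the tie-grouped ROC equals the
    # pairwise statistic
    trap = roc_curve(scores, labels).trapezoid_area()
    if abs(trap - a) > 1e-9:
        raise RuntimeError(
            f"trapezoid/Mann-Whitney mismatch: {trap!r} vs {a!r}"
        )
    se = _auc_se(v10, v01)
    return AUCResult(
        auc=a,
        se=se,
        ci_low=max(0.0, a - 1.96 * se),
        ci_high=min(1.0, a + 1.96 * se),
    )


def delong_compare(scores_a, scores_b, labels) -> PairedAUCTest:
    """Chi-square (1 df) equality test for two correlated AUCs.

    Both scores must be measured on the same patients with the same labels.
    The variance of the AUC difference is built from the empirical
    covariance of the paired placement values.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    v10a, v01a = delong_components(scores_a, labels)
    v10b, v01b = delong_components(scores_b, labels)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    delta = auc_a - auc_b

    def _cov(u, v):
        if u.size < 2:
            return np.zeros((2, 2))
        return np.cov(np.vstack([u, v]), ddof=1)

    s10 = _cov(v10a, v10b)
    s01 = _cov(v01a, v01b)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / v10a.size \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / v01a.size

    if var <= 1e-14:
        if abs(delta) < 1e-12:
            return PairedAUCTest(auc_a, auc_b, delta, chi2=0.0, p=1.0)
        raise DegenerateVarianceError(
            f"zero variance for a non-zero AUC difference ({delta})"
        )
    chi2 = delta * delta / var
    p = float(chi2_dist.sf(chi2, df=1))
    return PairedAUCTest(auc_a, auc_b, delta, chi2=float(chi2), p=p)
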