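"""Brute-force reference implementations used only by the test suite.

Deliberately naive (exhaustive enumeration, exact rational arithmetic) and
independent of the package's vectorized code paths.
"""

from fractions import Fraction

import numpy as np


def brute_auc(scores, labels):
    """Exact pairwise Mann-Whitney AUC (ties count 1/2) as a Fraction."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                total += 1
            elif p == q:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


def brute_roc_points(scores, labels):
    """(threshold, sensitivity, fpr) at every distinct score plus +inf."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    points = []
    for t in sorted(set(scores)) + [float("inf")]:
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= t)
        fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= t)
        points.append((t, Fraction(tp, n_pos), Fraction(fp, n_neg)))
    return points


def brute_confusion(scores, labels, cutoff):
    tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= cutoff)
    fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s < cutoff)
    tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < cutoff)
    fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= cutoff)
    return (
        Fraction(tp, tp + fn),
        Fraction(tn, tn + fp),
        Fraction(tp + tn, len(labels)),
    )


def brute_cutpoint(scores, labels):
    """Exact Youden scan; ties to higher specificity, then higher cutoff."""
    candidates = sorted(set(map(float, scores))) + [max(scores) + 1.0]
    best_key, best = None, None
    for c in candidates:
        sens, spec, acc = brute_confusion(scores, labels, c)
        key = (sens + spec, spec, c)
        if best_key is None or key > best_key:
            best_key, best = key, (c, sens, spec, acc)
    return best


def brute_search(base_scores, categories, labels, assignments):
    """Winner under exact AUC with (smaller sum, lexicographic) tie-break."""
    best_key, best = None, None
    for assignment in assignments:
        subs = assignment.sub_scores
        scores = [b + subs[c] for b, c in zip(base_scores, categories)]
        a = brute_auc(scores, labels)
        key = (-a, sum(subs), subs)
        if best_key is None or key < best_key:
            best_key, best = key, assignment
    return best


def pairwise_auc(pos, neg):
    """AUC by explicit pairwise comparison (vectorized but still brute)."""
    pos = np.asarray(pos, dtype=float)[:, None]
    neg = np.asarray(neg, dtype=float)[None, :]
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))


def stratified_bootstrap_var_delta(scores_a, scores_b, labels, n_boot, rng):
    """Bootstrap variance of the paired AUC difference (stratified by class)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        deltas[b] = pairwise_auc(scores_a[pi], scores_a[ni]) - pairwise_auc(
            scores_b[pi], scores_b[ni]
        )
    return float(np.var(deltas, ddof=1))
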