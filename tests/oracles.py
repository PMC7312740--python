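"""Independent brute-force oracles used by the test suite.

These implementations deliberately mirror the mathematical definitions with
explicit loops and stay independent of the package's vectorised code paths.
"""
import math

import numpy as np


def cross_sample_entropy_bruteforce(u, v, m, r):
    """Exhaustive O(N^2) cross-sample entropy.

    Template pairs of lengths m and m+1 (both over the first N-m start
    positions), Chebyshev distance, explicit double loop.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(u)
    n_templates = n - m

    def b(mm):
        total = 0.0
        for i in range(n_templates):
            count = 0
            for j in range(n_templates):
                d = 0.0
                for k in range(mm):
                    d = max(d, abs(u[i + k] - v[j + k]))
                if d <= r:
                    count += 1
            total += count / n_templates
        return total / n_templates

    bm = b(m)
    bm1 = b(m + 1)
    if bm == 0.0 or bm1 == 0.0:
        return float("nan")
    return -math.log(bm1 / bm)


def auc_by_rank_statistic(scores, labels):
    """AUC as the Mann-Whitney U statistic over positive/negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
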