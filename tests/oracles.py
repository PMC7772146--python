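"""Independent brute-force oracles used by the test suite.

These deliberately use naive loops / exhaustive enumeration and share
no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm


def brute_sample_entropy(y, m, r):
    """Sample entropy by direct template counting.

    Templates Y_i = (y_i .. y_{i+mm-1}) for i = 1 .. N-mm+1; per-template
    similarity counts (j != i, Chebyshev distance strictly < r) divided
    by N-mm; averaged over all templates; repeated at mm = m+1;
    -ln(B^{m+1}/B^m).  Returns nan when a count vanishes or r <= 0.
    """
    y = list(map(float, y))
    n = len(y)
    if not r > 0:
        return math.nan

    def avg_similarity(mm):
        n_templates = n - mm + 1
        per_template = []
        for i in range(n_templates):
            count = 0
            for j in range(n_templates):
                if j == i:
                    continue
                d = max(abs(y[i + k] - y[j + k]) for k in range(mm))
                if d < r:
                    count += 1
            per_template.append(count / (n - mm))
        return sum(per_template) / n_templates

    b_m = avg_similarity(m)
    b_m1 = avg_similarity(m + 1)
    if b_m == 0.0 or b_m1 == 0.0:
        return math.nan
    return -math.log(b_m1 / b_m)


def brute_forward_loglik(startprob, transmat, means, variances, seq):
    """log P(O | lambda) by exhaustive enumeration of all state paths."""
    seq = np.atleast_2d(seq)
    T = seq.shape[0]
    q = len(startprob)
    total = -np.inf
    for path in itertools.product(range(q), repeat=T):
        lp = math.log(startprob[path[0]]) if startprob[path[0]] > 0 else -math.inf
        for t in range(1, T):
            a = transmat[path[t - 1], path[t]]
            if a <= 0:
                lp = -math.inf
                break
            lp += math.log(a)
        if lp == -math.inf:
            continue
        for t in range(T):
            lp += float(
                norm.logpdf(
                    seq[t], loc=means[path[t]], scale=np.sqrt(variances[path[t]])
                ).sum()
            )
        total = np.logaddexp(total, lp)
    return float(total)
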