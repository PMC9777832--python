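"""Independent naive reference implementations used as test oracles.

Everything here is written with explicit Python loops and the standard
library only, so it shares no code path with the package's vectorized
implementations.
"""

from __future__ import annotations

import math


def naive_entropies(x, m: int = 2, r_coeff: float = 0.15) -> tuple[float, float]:
    """(ApEn, SampEn) by direct O(N^2) enumeration.

    Strict ``d < r`` matching under the Chebyshev distance; ApEn includes the
    self comparison, SampEn excludes it; ``r = r_coeff * population STD``;
    constant series return (0, 0); a zero SampEn match count is floored at
    one matching ordered pair.
    """
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if std == 0.0:
        return 0.0, 0.0
    r = r_coeff * std

    def match_counts(mm: int) -> list[int]:
        n_templates = n - mm + 1
        counts = [0] * n_templates
        for i in range(n_templates):
            for j in range(n_templates):
                d = 0.0
                for k in range(mm):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                if d < r:
                    counts[i] += 1
        return counts

    c_m = match_counts(m)
    c_m1 = match_counts(m + 1)

    phi_m = sum(math.log(c / (n - m + 1)) for c in c_m) / (n - m + 1)
    phi_m1 = sum(math.log(c / (n - m)) for c in c_m1) / (n - m)
    ap = phi_m - phi_m1

    a_m = sum(c - 1 for c in c_m) / ((n - m) * (n - m + 1))
    a_m1 = sum(c - 1 for c in c_m1) / ((n - m - 1) * (n - m))
    if a_m == 0.0:
        a_m = 1.0 / ((n - m) * (n - m + 1))
    if a_m1 == 0.0:
        a_m1 = 1.0 / ((n - m - 1) * (n - m))
    se = math.log(a_m) - math.log(a_m1)
    return ap, se


def naive_knn(train_x, train_y, test_x, k: int = 2) -> list:
    """Exhaustive-distance KNN with the package's tie-breaking contract.

    Neighbours ranked by (euclidean distance, training row index); majority
    vote among the first k; a vote tie goes to the tied label whose
    representative comes first in the ranking.
    """
    preds = []
    for q in test_x:
        ranked = sorted(
            range(len(train_x)),
            key=lambda j: (
                math.sqrt(sum((a - b) ** 2 for a, b in zip(train_x[j], q))),
                j,
            ),
        )
        nn = ranked[:k]
        votes: dict = {}
        for j in nn:
            votes[train_y[j]] = votes.get(train_y[j], 0) + 1
        top = max(votes.values())
        tied = {lab for lab, v in votes.items() if v == top}
        if len(tied) == 1:
            preds.append(next(iter(tied)))
        else:
            preds.append(next(train_y[j] for j in nn if train_y[j] in tied))
    return preds
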