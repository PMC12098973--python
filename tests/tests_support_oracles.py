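"""Independent small-instance oracles shared by the test suite.

These are deliberately naive re-derivations (contingency formula, per-point
definition) kept separate from the package implementation they check.
"""

import numpy as np


def ari_oracle(a, b):
    """Adjusted Rand index straight from the contingency-table formula."""
    from math import comb

    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    sum_ij = sum(
        comb(int(np.sum((a == i) & (b == j))), 2) for i in set(a) for j in set(b)
    )
    sum_i = sum(comb(int(np.sum(a == i)), 2) for i in set(a))
    sum_j = sum(comb(int(np.sum(b == j)), 2) for j in set(b))
    expected = sum_i * sum_j / comb(n, 2)
    max_index = (sum_i + sum_j) / 2
    return (sum_ij - expected) / (max_index - expected)


def silhouette_oracle(X, labels):
    """Mean silhouette from the per-point definition."""
    X, labels = np.asarray(X, float), np.asarray(labels)
    n = len(X)
    dist = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        a = dist[i, same].mean() if same.any() else 0.0
        b = min(
            dist[i, labels == other].mean()
            for other in set(labels)
            if other != labels[i]
        )
        scores.append(0.0 if not same.any() else (b - a) / max(a, b))
    return float(np.mean(scores))
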