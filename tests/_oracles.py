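"""Independent oracle implementations used to pin expected values.

Everything here is deliberately naive (enumeration, Counter histograms,
grid search) and shares no code with the package paths it checks.
"""
from __future__ import annotations

from collections import Counter

import numpy as np

MISSING = "MISSING"


def set_partitions(items):
    """Yield every partition of a list (restricted growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def modularity_pairsum(weights, labels):
    """Modularity by literal double sum over all vertex pairs.

    The null-model term runs over every ordered pair including i == j
    (A_ii = 0), matching the standard Newman-Girvan definition.
    """
    w = np.asarray(weights, float)
    n = w.shape[0]
    labels = list(labels)
    m2 = sum(w[i, j] for i in range(n) for j in range(n) if i != j)
    if m2 == 0:
        return 0.0
    k = [sum(w[i, j] for j in range(n) if j != i) for i in range(n)]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            a_ij = w[i, j] if i != j else 0.0
            q += (a_ij - k[i] * k[j] / m2) / m2
    return q


def partition_labelings(n):
    """Yield every partition of n items as a label vector.

    Iterative restricted-growth-string enumeration; label vectors reuse a
    buffer, so copy before storing.
    """
    labels = np.zeros(n, dtype=int)
    maxes = np.zeros(n, dtype=int)
    yield labels
    while True:
        i = n - 1
        while i > 0 and labels[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxes[j] = maxes[i]
        yield labels


def modularity_dense(weights, labels):
    """Definitional modularity as one masked double sum (diag A = 0)."""
    w = np.asarray(weights, float)
    k = w.sum(axis=1)
    m2 = w.sum()
    if m2 == 0:
        return 0.0
    same = np.asarray(labels)[:, None] == np.asarray(labels)[None, :]
    return float(((w - np.outer(k, k) / m2) * same).sum() / m2)


def best_partition_bruteforce(weights):
    """Globally maximal-modularity partition by exhaustive enumeration."""
    n = np.asarray(weights).shape[0]
    best_q, best_labels = -np.inf, None
    for partition in set_partitions(range(n)):
        labels = [0] * n
        for c, block in enumerate(partition):
            for v in block:
                labels[v] = c
        q = modularity_pairsum(weights, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def entropy_bits_oracle(rows):
    """Per-slot-averaged entropy from Counter histograms (bits)."""
    rows = [list(r) for r in rows]
    n_slots = len(rows[0])
    hs = []
    for j in range(n_slots):
        col = [r[j] for r in rows if r[j] != MISSING]
        if not col:
            continue
        counts = Counter(col)
        total = sum(counts.values())
        h = -sum((c / total) * np.log2(c / total) for c in counts.values())
        hs.append(h)
    return float(np.mean(hs))


def clustered_entropy_oracle(rows, labels):
    rows = [list(r) for r in rows]
    n = len(rows)
    total = 0.0
    for c in set(labels):
        block = [rows[i] for i in range(n) if labels[i] == c]
        total += len(block) / n * entropy_bits_oracle(block)
    return total


def alpha_grid_search(samples, xmax, grid=None):
    """Exact discrete power-law log-likelihood maximized on a coarse grid."""
    x = np.asarray(samples, float)
    if grid is None:
        grid = np.arange(1.05, 4.0, 0.001)
    support = np.arange(1, xmax + 1, dtype=float)
    best_a, best_ll = None, -np.inf
    log_x_sum = np.log(x).sum()
    for a in grid:
        z = (support**-a).sum()
        ll = -a * log_x_sum - len(x) * np.log(z)
        if ll > best_ll:
            best_a, best_ll = a, ll
    return float(best_a)
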