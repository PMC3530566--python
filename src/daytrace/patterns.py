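"""Per-user day-pattern discovery.

Two routes, compared on equal footing:

* community detection on a complete weighted day graph (weights a smooth
  decreasing function of the weighted Hamming distance between day
  vectors) with a tau-EO modularity maximizer, whose cluster count is an
  emergent outcome; and
* Euclidean k-means on the one-hot ("binary expansion") encoding of day
  vectors, best of ``n_runs`` random restarts.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from .core import MISSING, DayMatrix
from .locstats import LocationAlphabet, location_frequencies

_TOL = 1e-12


# ---------------------------------------------------------------------------
# distances and the day graph


def day_distance(d1, d2, slot_weights=None) -> float:
    """Weighted Hamming distance between two day vectors.

    ``D = sum_j u_j * [d1_j != d2_j]`` over slots where both vectors are
    observed; when some slots are MISSING the sum is rescaled by
    ``sum(u) / sum(u over compared slots)`` so distances stay comparable
    across days with different coverage.  Two days with no comparable slot
    get the maximal distance ``sum(u)``.
    """
    a = np.asarray(d1, dtype=object)
    b = np.asarray(d2, dtype=object)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("day vectors must be 1-d and equally long")
    u = np.ones(len(a)) if slot_weights is None else np.asarray(slot_weights, float)
    if len(u) != len(a):
        raise ValueError("slot_weights length mismatch")
    compared = (a != MISSING) & (b != MISSING)
    total_w = u.sum()
    cmp_w = u[compared].sum()
    if cmp_w == 0:
        return float(total_w)
    raw = float(u[compared & (a != b)].sum())
    return raw * total_w / cmp_w


def pairwise_distances(days: np.ndarray, slot_weights=None) -> np.ndarray:
    days = np.asarray(days, dtype=object)
    n = days.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = day_distance(days[i], days[j], slot_weights)
    return out


@dataclasses.dataclass
class DayGraph:
    """Complete similarity graph over a user's days (diagonal zeroed)."""

    weights: np.ndarray
    delta: float

    @property
    def n_days(self) -> int:
        return self.weights.shape[0]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        n = self.n_days
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                g.add_edge(i, j, weight=float(self.weights[i, j]))
        return g


def build_day_graph(
    matrix: DayMatrix, delta: float | None = None, slot_weights=None
) -> DayGraph:
    """Similarity graph with ``w = exp(-D / delta)``, default delta = n_slots/4."""
    if matrix.n_days < 2:
        raise ValueError("need at least 2 days to build a day graph")
    if delta is None:
        delta = matrix.n_slots / 4.0
    if delta <= 0:
        raise ValueError("delta must be positive")
    dist = pairwise_distances(matrix.slots, slot_weights)
    w = np.exp(-dist / delta)
    np.fill_diagonal(w, 0.0)
    return DayGraph(w, float(delta))


def inverse_frequency_weights(matrix: DayMatrix) -> np.ndarray:
    """Optional slot weights u_j = 1 / (mean label frequency at slot j)."""
    alphabet = location_frequencies(matrix)
    freq = dict(zip(alphabet.entries["location_id"], alphabet.entries["freq"]))
    out = np.ones(matrix.n_slots)
    for j in range(matrix.n_slots):
        col = [freq[v] for v in matrix.slots[:, j] if v != MISSING]
        if col:
            out[j] = 1.0 / float(np.mean(col))
    return out / out.mean()


# ---------------------------------------------------------------------------
# modularity and extremal optimization


@dataclasses.dataclass
class ClusterAssignment:
    """Partition of a user's days into pattern labels."""

    labels: np.ndarray
    method: str
    score: float  # modularity (eo) or negative inertia (kmeans)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def modularity(weights: np.ndarray, labels: Sequence[int]) -> float:
    """Weighted Newman-Girvan modularity of a partition (diag ignored)."""
    w = np.asarray(weights, float).copy()
    np.fill_diagonal(w, 0.0)
    labels = np.asarray(labels)
    m2 = w.sum()
    if m2 <= 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += w[np.ix_(mask, mask)].sum() / m2 - (k[mask].sum() / m2) ** 2
    return float(q)


def _tau_probs(n: int, tau: float) -> np.ndarray:
    p = np.arange(1, n + 1, dtype=float) ** (-tau)
    return p / p.sum()


def _eo_bisect(wc, kc, m2, tau, rng, sweeps=40, patience_sweeps=12):
    """tau-EO bipartition of one community; returns (sigma, delta_Q).

    ``wc`` is the community-induced weight block, ``kc`` the full-graph
    strengths of its vertices, ``m2`` the full graph's total weight.
    delta_Q is the change in full-graph modularity if the community is
    split along sigma.
    """
    n = wc.shape[0]
    kin = wc.sum(axis=1)
    kin_tot = kin.sum()
    w_cc = wc.sum()
    s_c = kc.sum()

    sigma = rng.integers(0, 2, size=n)
    if sigma.all() or not sigma.any():
        sigma[rng.integers(n)] ^= 1

    side1 = sigma.astype(bool)
    kappa = np.where(side1, wc @ side1, wc @ ~side1)
    w_in = np.array([kappa[~side1].sum(), kappa[side1].sum()])
    s_full = np.array([kc[~side1].sum(), kc[side1].sum()])
    kin_side = np.array([kin[~side1].sum(), kin[side1].sum()])

    def split_dq():
        return (w_in.sum() - w_cc) / m2 - (
            s_full[0] ** 2 + s_full[1] ** 2 - s_c**2
        ) / m2**2

    probs = _tau_probs(n, tau)
    best_sigma = sigma.copy()
    best_dq = split_dq()
    stall, max_steps = 0, max(sweeps * n, 64)
    patience = max(patience_sweeps * n, 32)
    for _ in range(max_steps):
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(kin > 0, kappa / np.where(kin > 0, kin, 1.0), 0.0)
        fitness = ratio - (kin_side[sigma] / kin_tot if kin_tot > 0 else 0.0)
        order = np.argsort(fitness, kind="stable")
        idx = order[rng.choice(n, p=probs)]
        a = int(sigma[idx])
        b = 1 - a
        w_in[a] -= 2.0 * kappa[idx]
        in_a = sigma == a
        in_b = ~in_a
        kappa[in_a] -= wc[in_a, idx]
        kappa[in_b] += wc[in_b, idx]
        kappa[idx] = wc[idx] @ in_b
        w_in[b] += 2.0 * kappa[idx]
        s_full[a] -= kc[idx]
        s_full[b] += kc[idx]
        kin_side[a] -= kin[idx]
        kin_side[b] += kin[idx]
        sigma[idx] = b
        dq = split_dq()
        if dq > best_dq + _TOL:
            best_dq = dq
            best_sigma = sigma.copy()
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    return best_sigma, float(best_dq)


def _refine(w, labels, max_passes=60):
    """Greedy single-vertex moves (including to a fresh community)."""
    n = w.shape[0]
    labels = labels.copy()
    m2 = w.sum()
    if m2 <= 0:
        return labels
    k = w.sum(axis=1)
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            n_lab = labels.max() + 2  # existing labels + one empty slot
            kappa = np.bincount(labels, weights=w[i], minlength=n_lab)
            s = np.bincount(labels, weights=k, minlength=n_lab)
            a = labels[i]
            s_a_out = s[a] - k[i]
            gain = 2.0 * (kappa - kappa[a]) / m2 - (
                (s + k[i]) ** 2 - s**2 + s_a_out**2 - s[a] ** 2
            ) / m2**2
            gain[a] = 0.0
            b = int(np.argmax(gain))
            if gain[b] > _TOL:
                labels[i] = b
                improved = True
        if not improved:
            break
    # compact relabel, stable in first-appearance order
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def eo_modularity(
    graph: DayGraph | np.ndarray,
    tau: float = 1.4,
    rng=None,
    restarts: int = 4,
    sweeps: int = 40,
) -> ClusterAssignment:
    """Duch-Arenas style extremal-optimization modularity clustering.

    Recursive bisection: each community is repeatedly offered a tau-EO
    bipartition and split whenever that increases full-graph modularity;
    the recursion therefore decides the number of clusters by itself.  A
    greedy single-move refinement pass follows, and the best of
    ``restarts`` seeded runs is returned.
    """
    w = graph.weights if isinstance(graph, DayGraph) else np.asarray(graph, float)
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    rng = np.random.default_rng(rng)
    if n == 1 or w.sum() <= 0:
        return ClusterAssignment(np.zeros(n, dtype=int), "eo", 0.0)

    k = w.sum(axis=1)
    m2 = w.sum()
    best_labels, best_q = np.zeros(n, dtype=int), 0.0
    for _ in range(max(restarts, 1)):
        labels = np.zeros(n, dtype=int)
        queue = [np.arange(n)]
        next_label = 1
        while queue:
            idx = queue.pop()
            if len(idx) < 2:
                continue
            sigma, dq = _eo_bisect(
                w[np.ix_(idx, idx)], k[idx], m2, tau, rng, sweeps=sweeps
            )
            if dq > _TOL and sigma.any() and not sigma.all():
                moved = idx[sigma.astype(bool)]
                labels[moved] = next_label
                next_label += 1
                queue.append(idx[~sigma.astype(bool)])
                queue.append(moved)
        labels = _refine(w, labels)
        q = modularity(w, labels)
        if q > best_q + _TOL:
            best_labels, best_q = labels, q
    return ClusterAssignment(best_labels, "eo", float(best_q))


# ---------------------------------------------------------------------------
# k-means on the binary expansion


def one_hot_days(matrix: DayMatrix) -> tuple[np.ndarray, list[str]]:
    """One-hot encode day vectors: (n_days, n_slots * |alphabet|).

    MISSING slots encode as all-zero blocks.
    """
    alphabet = matrix.labels()
    index = {lab: i for i, lab in enumerate(alphabet)}
    a = len(alphabet)
    x = np.zeros((matrix.n_days, matrix.n_slots * a))
    for d in range(matrix.n_days):
        for j in range(matrix.n_slots):
            v = matrix.slots[d, j]
            if v != MISSING:
                x[d, j * a + index[v]] = 1.0
    return x, alphabet


def kmeans_days(
    matrix: DayMatrix, k: int, n_runs: int = 200, random_state: int = 0
) -> ClusterAssignment:
    """Best-of-``n_runs`` Euclidean k-means on one-hot day vectors."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.n_days:
        raise ValueError("k exceeds the number of days")
    x, _ = one_hot_days(matrix)
    km = KMeans(n_clusters=k, n_init=n_runs, random_state=random_state)
    labels = km.fit_predict(x)
    return ClusterAssignment(labels.astype(int), "kmeans", float(-km.inertia_))


# ---------------------------------------------------------------------------
# cluster profiles


@dataclasses.dataclass
class ClusterProfile:
    average_days: np.ndarray  # (n_clusters, n_slots) object
    deviation_masks: np.ndarray  # (n_days, n_slots) bool
    rank_enrichment: float | None  # mean rank in deviations minus agreements
    sizes: np.ndarray


def _modal_label(values) -> str:
    vals = [v for v in values if v != MISSING]
    if not vals:
        return MISSING
    labs, counts = np.unique(np.asarray(vals, dtype=object).astype(str), return_counts=True)
    order = np.lexsort((labs, -counts))
    return str(labs[order[0]])


def cluster_profile(
    matrix: DayMatrix,
    assignment: ClusterAssignment,
    alphabet: LocationAlphabet | None = None,
) -> ClusterProfile:
    """Average day (per-slot mode) and deviation masks per cluster.

    Rank enrichment compares the mean location rank of deviating slots to
    agreeing slots; tail-biased noise shows up as a positive value.
    """
    labels = np.asarray(assignment.labels)
    if len(labels) != matrix.n_days:
        raise ValueError("assignment does not match the day matrix")
    clusters = np.unique(labels)
    if any(np.sum(labels == c) == 0 for c in clusters):
        raise ValueError("empty cluster")
    n_c, n_slots = len(clusters), matrix.n_slots
    avg = np.empty((n_c, n_slots), dtype=object)
    for ci, c in enumerate(clusters):
        block = matrix.slots[labels == c]
        for j in range(n_slots):
            avg[ci, j] = _modal_label(block[:, j])
    cluster_pos = {c: i for i, c in enumerate(clusters)}
    dev = np.zeros((matrix.n_days, n_slots), dtype=bool)
    for d in range(matrix.n_days):
        ref = avg[cluster_pos[labels[d]]]
        row = matrix.slots[d]
        dev[d] = (row != MISSING) & (row != ref)

    if alphabet is None:
        alphabet = location_frequencies(matrix)
    rank = alphabet.rank_of()
    observed = matrix.slots != MISSING
    dev_ranks = [rank[v] for v in matrix.slots[dev & observed]]
    agree_ranks = [rank[v] for v in matrix.slots[~dev & observed]]
    enrichment = None
    if dev_ranks and agree_ranks:
        enrichment = float(np.mean(dev_ranks) - np.mean(agree_ranks))
    sizes = np.array([int(np.sum(labels == c)) for c in clusters])
    return ClusterProfile(avg, dev, enrichment, sizes)
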