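"""Next-location prediction quality estimators.

Four methods: a static guess from per-slot occupancy distributions and a
transition-matrix guess from empirical conditional distributions
P(location at j+lag | location at j), each computed with or without
conditioning on day patterns.  Two guess rules are supported:

* ``matching`` (default) — guess by sampling the estimated distribution;
  expected success sum(p^2) (respectively the mean probability the model
  assigns to the realized outcome);
* ``mode`` — always guess the most probable location; success max(p).
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import MISSING, DayMatrix

RULES = ("matching", "mode")


def _check_rule(rule: str) -> None:
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


# ---------------------------------------------------------------------------
# static (occupancy) method


@dataclasses.dataclass
class OccupancyModel:
    """Per-slot location distributions, optionally split by cluster."""

    alphabet: list[str]
    p: np.ndarray  # (n_slots, A); NaN rows where a slot is unobserved
    per_cluster: dict[int, np.ndarray] | None = None
    cluster_weights: dict[int, float] | None = None


def _slot_distributions(slots: np.ndarray, index: Mapping[str, int]) -> np.ndarray:
    n_slots = slots.shape[1]
    p = np.full((n_slots, len(index)), np.nan)
    for j in range(n_slots):
        vals = slots[:, j][slots[:, j] != MISSING]
        if len(vals) == 0:
            continue
        row = np.zeros(len(index))
        for v in vals:
            row[index[v]] += 1
        p[j] = row / row.sum()
    return p


def fit_occupancy(
    matrix: DayMatrix, assignment: Sequence[int] | None = None
) -> OccupancyModel:
    alphabet = matrix.labels()
    index = {lab: i for i, lab in enumerate(alphabet)}
    p = _slot_distributions(matrix.slots, index)
    per_cluster = None
    weights = None
    if assignment is not None:
        labels = np.asarray(assignment)
        per_cluster = {}
        weights = {}
        for c in np.unique(labels):
            mask = labels == c
            per_cluster[int(c)] = _slot_distributions(matrix.slots[mask], index)
            weights[int(c)] = float(mask.sum() / matrix.n_days)
    return OccupancyModel(alphabet, p, per_cluster, weights)


def _rule_quality(p_row: np.ndarray, rule: str) -> float:
    return float(np.max(p_row)) if rule == "mode" else float(np.sum(p_row**2))


@dataclasses.dataclass
class StaticReport:
    per_slot: np.ndarray
    day_average: float
    rule: str
    with_patterns: bool


def static_quality(
    matrix: DayMatrix,
    assignment: Sequence[int] | None = None,
    rule: str = "matching",
) -> StaticReport:
    """Static guess quality per slot and day-averaged.

    Without patterns, Q_j is the rule quality of the slot-j occupancy
    distribution; with patterns, the n_c/N-weighted average of the
    per-cluster qualities (weights renormalized over clusters observed at
    the slot).
    """
    _check_rule(rule)
    model = fit_occupancy(matrix, assignment)
    n_slots = matrix.n_slots
    q = np.full(n_slots, np.nan)
    for j in range(n_slots):
        if assignment is None:
            if not np.isnan(model.p[j]).any():
                q[j] = _rule_quality(model.p[j], rule)
        else:
            acc, wsum = 0.0, 0.0
            for c, pc in model.per_cluster.items():
                if np.isnan(pc[j]).any():
                    continue
                w = model.cluster_weights[c]
                acc += w * _rule_quality(pc[j], rule)
                wsum += w
            if wsum > 0:
                q[j] = acc / wsum
    ok = ~np.isnan(q)
    if not ok.any():
        raise ValueError("no observable slots")
    return StaticReport(q, float(q[ok].mean()), rule, assignment is not None)


# ---------------------------------------------------------------------------
# transition (transfer-matrix) method


@dataclasses.dataclass
class TransitionModel:
    """Empirical P(location at j+lag | location at j).

    ``counts`` has shape (n_slots, A, A) (origin slot, origin, target), or
    (A, A) when slot-pooled.  Per-cluster count tensors are kept when the
    model was fitted with an assignment.
    """

    alphabet: list[str]
    lag: int
    counts: np.ndarray
    pooled: bool
    per_cluster: dict[int, np.ndarray] | None = None
    cluster_weights: dict[int, float] | None = None
    assignment: np.ndarray | None = None  # day -> cluster, kept for scoring

    def row(self, slot: int, origin: int, cluster: int | None = None) -> np.ndarray | None:
        """Normalized row, or None when undefined (no observed pairs)."""
        counts = self.counts if cluster is None else self.per_cluster[cluster]
        row = counts[origin] if self.pooled else counts[slot, origin]
        total = row.sum()
        if total == 0:
            return None
        return row / total


def _calendar_sequence(matrix: DayMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated slot labels over the full calendar span.

    Days absent from the matrix (filtered out) appear as MISSING rows, so
    pairs never bridge an excluded day.  Returns (labels flat array,
    day-row index per flat position; -1 on absent days).
    """
    n_slots = matrix.n_slots
    start, end = matrix.dates[0], matrix.dates[-1]
    n_days = (end - start).days + 1
    flat = np.full(n_days * n_slots, MISSING, dtype=object)
    day_of = np.full(n_days * n_slots, -1, dtype=int)
    for r, d in enumerate(matrix.dates):
        o = (d - start).days * n_slots
        flat[o : o + n_slots] = matrix.slots[r]
        day_of[o : o + n_slots] = r
    return flat, day_of


def fit_transition_model(
    matrix: DayMatrix,
    lag: int = 1,
    assignment: Sequence[int] | None = None,
    pooled: bool = False,
) -> TransitionModel:
    """Count location pairs (slot j, slot j+lag) over the calendar sequence.

    Pairs cross midnight via calendar concatenation; pairs with a MISSING
    member are skipped.  With an assignment, counts are additionally split
    by the origin day's cluster.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    alphabet = matrix.labels()
    index = {lab: i for i, lab in enumerate(alphabet)}
    a = len(alphabet)
    n_slots = matrix.n_slots
    flat, day_of = _calendar_sequence(matrix)
    shape = (a, a) if pooled else (n_slots, a, a)
    counts = np.zeros(shape)
    per_cluster = None
    weights = None
    if assignment is not None:
        labels = np.asarray(assignment)
        per_cluster = {int(c): np.zeros(shape) for c in np.unique(labels)}
        weights = {
            int(c): float(np.sum(labels == c) / matrix.n_days)
            for c in np.unique(labels)
        }
    for t in range(len(flat) - lag):
        x, y = flat[t], flat[t + lag]
        if x == MISSING or y == MISSING:
            continue
        i, k = index[x], index[y]
        j = t % n_slots
        if pooled:
            counts[i, k] += 1
        else:
            counts[j, i, k] += 1
        if per_cluster is not None:
            c = int(np.asarray(assignment)[day_of[t]])
            if pooled:
                per_cluster[c][i, k] += 1
            else:
                per_cluster[c][j, i, k] += 1
    kept = None if assignment is None else np.asarray(assignment)
    return TransitionModel(alphabet, lag, counts, pooled, per_cluster, weights, kept)


@dataclasses.dataclass
class TransitionReport:
    per_slot: np.ndarray
    overall: float
    n_pairs: int
    n_skipped: int  # pairs whose origin row was undefined
    rule: str
    with_patterns: bool
    lag: int


def transition_quality(
    model: TransitionModel,
    matrix: DayMatrix,
    rule: str = "matching",
) -> TransitionReport:
    """In-sample guess quality of a fitted transition model.

    Matching rule scores each pair by the probability the origin row gives
    the realized target (averaging to sum over rows of p_a * sum_b T(a,b)^2);
    mode rule scores 1 when the row's argmax is the realized target.
    """
    _check_rule(rule)
    index = {lab: i for i, lab in enumerate(model.alphabet)}
    n_slots = matrix.n_slots
    flat, day_of = _calendar_sequence(matrix)
    num = np.zeros(n_slots)
    den = np.zeros(n_slots)
    skipped = 0
    for t in range(len(flat) - model.lag):
        x, y = flat[t], flat[t + model.lag]
        if x == MISSING or y == MISSING:
            continue
        j = t % n_slots
        cluster = None
        if model.per_cluster is not None:
            cluster = int(model.assignment[day_of[t]])
        row = model.row(j, index[x], cluster)
        if row is None:
            skipped += 1
            continue
        if rule == "mode":
            num[j] += 1.0 if index[y] == int(np.argmax(row)) else 0.0
        else:
            num[j] += float(row[index[y]])
        den[j] += 1
    ok = den > 0
    per_slot = np.full(n_slots, np.nan)
    per_slot[ok] = num[ok] / den[ok]
    total = den.sum()
    if total == 0:
        raise ValueError("no observable transition pairs")
    return TransitionReport(
        per_slot,
        float(num.sum() / total),
        int(total),
        skipped,
        rule,
        model.per_cluster is not None,
        model.lag,
    )


# ---------------------------------------------------------------------------
# long-range curves and panel correlation


@dataclasses.dataclass
class LongRangeCurve:
    lags: np.ndarray
    quality: np.ndarray
    fit_intercept: float  # Q ~ a - b log(lag)
    fit_slope: float  # the b above (positive = decaying)
    stays_above_static: bool
    truncated_at: int | None


def long_range_curve(
    matrix: DayMatrix,
    max_lag: int = 12,
    rule: str = "matching",
    assignment: Sequence[int] | None = None,
) -> LongRangeCurve:
    """Transition quality as a function of the lag, with a log fit."""
    _check_rule(rule)
    lags, qs = [], []
    truncated = None
    for lag in range(1, max_lag + 1):
        model = fit_transition_model(matrix, lag=lag, assignment=assignment)
        try:
            rep = transition_quality(model, matrix, rule)
        except ValueError:
            truncated = lag
            break
        lags.append(lag)
        qs.append(rep.overall)
    lags_arr = np.array(lags)
    q_arr = np.array(qs)
    if len(lags_arr) >= 2:
        b, a = np.polyfit(np.log(lags_arr), q_arr, 1)
    else:
        a, b = (q_arr[0] if len(q_arr) else np.nan), 0.0
    static_avg = static_quality(matrix, None, rule).day_average
    return LongRangeCurve(
        lags_arr,
        q_arr,
        float(a),
        float(-b),
        bool(len(q_arr) > 0 and np.all(q_arr >= static_avg - 1e-9)),
        truncated,
    )


def entropy_predictability_correlation(
    entropies: Sequence[float], qualities: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of personal entropy against quality.

    Raises on fewer than 3 users or degenerate (constant) inputs.
    """
    s = np.asarray(entropies, float)
    q = np.asarray(qualities, float)
    if len(s) != len(q) or len(s) < 3:
        raise ValueError("need >= 3 paired (entropy, quality) observations")
    if np.ptp(s) == 0 or np.ptp(q) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    rho, p = stats.spearmanr(s, q)
    return float(rho), float(p)
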