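"""Bare, clustered, and null-model life entropies (bits).

The bare entropy averages per-slot Shannon entropies of the slot-location
histograms over a user's accepted days.  The clustered entropy is the
cluster-size-weighted average of the same quantity computed within each
cluster; the drop between the two measures how much apparent randomness is
really pattern multiplicity.  The null model is the maximum entropy
compatible with a concentrated modal probability p0 and the residual mass
spread uniformly over the remaining locations.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

from .core import MISSING, DayMatrix


def _slot_entropy(column: np.ndarray) -> float | None:
    """Shannon entropy (bits) of one slot's non-MISSING label histogram."""
    vals = column[column != MISSING]
    if len(vals) == 0:
        return None
    _, counts = np.unique(vals.astype(str), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def slot_entropies(matrix: DayMatrix) -> np.ndarray:
    """Per-slot entropies; NaN where a slot has no observations."""
    out = np.full(matrix.n_slots, np.nan)
    for j in range(matrix.n_slots):
        h = _slot_entropy(matrix.slots[:, j])
        if h is not None:
            out[j] = h
    return out


def bare_entropy(matrix: DayMatrix) -> float:
    """Per-slot-averaged entropy of the user's slot-location histograms."""
    h = slot_entropies(matrix)
    ok = ~np.isnan(h)
    if not ok.all():
        warnings.warn(
            f"user {matrix.user_id}: {int((~ok).sum())} slot(s) with no "
            "observations skipped",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("no observable slots")
    return float(h[ok].mean())


def clustered_entropy(matrix: DayMatrix, labels: Sequence[int]) -> float:
    """Size-weighted average of within-cluster bare entropies."""
    labels = np.asarray(labels)
    if len(labels) != matrix.n_days:
        raise ValueError("assignment does not cover the day matrix")
    n = matrix.n_days
    total = 0.0
    for c in np.unique(labels):
        sub = matrix.subset(labels == c)
        total += sub.n_days / n * bare_entropy(sub)
    return float(total)


def entropy_drop(s_bare: float, s_clustered: float) -> tuple[float, float]:
    """(delta_S in bits, relative drop in percent).

    Relative drop is 0 when the bare entropy is 0.  A clustered entropy
    exceeding the bare one beyond numerical tolerance indicates an
    invariant violation on complete data and raises.
    """
    delta = s_bare - s_clustered
    if delta < -1e-9:
        raise ValueError(
            f"clustered entropy {s_clustered} exceeds bare entropy {s_bare}"
        )
    rel = 0.0 if s_bare == 0 else 100.0 * delta / s_bare
    return float(delta), float(rel)


def null_entropy(p0: float, n_locations: int) -> float:
    """Max entropy given modal mass p0 over ``n_locations`` symbols."""
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    if n_locations == 1:
        if not np.isclose(p0, 1.0):
            raise ValueError("p0 must be 1 for a single location")
        return 0.0
    if p0 < 1.0 / n_locations - 1e-12 or p0 > 1.0 + 1e-12:
        raise ValueError("p0 must lie in [1/n, 1]")
    p0 = min(p0, 1.0)
    rest = 1.0 - p0
    s = -p0 * np.log2(p0) if p0 > 0 else 0.0
    if rest > 0:
        s -= rest * np.log2(rest / (n_locations - 1))
    return float(s)


def modal_probability(matrix: DayMatrix) -> float:
    """Mean over slots of the empirical modal-location probability."""
    probs = []
    for j in range(matrix.n_slots):
        vals = matrix.slots[:, j][matrix.slots[:, j] != MISSING]
        if len(vals) == 0:
            continue
        _, counts = np.unique(vals.astype(str), return_counts=True)
        probs.append(counts.max() / counts.sum())
    if not probs:
        raise ValueError("no observable slots")
    return float(np.mean(probs))


@dataclasses.dataclass
class EntropyReport:
    user_id: str
    s_bare: float
    s_clustered: dict[str, float]  # method -> bits
    delta_s: dict[str, tuple[float, float]]  # method -> (bits, percent)
    s_null: float
    n_patterns: dict[str, int]
    n_significant_locations: int

    def to_record(self) -> dict:
        rec = {
            "user_id": self.user_id,
            "s_bare": self.s_bare,
            "s_null": self.s_null,
            "n_significant_locations": self.n_significant_locations,
        }
        for method, s in self.s_clustered.items():
            rec[f"s_clustered_{method}"] = s
            rec[f"delta_s_{method}"] = self.delta_s[method][0]
            rec[f"delta_s_rel_{method}"] = self.delta_s[method][1]
            rec[f"n_patterns_{method}"] = self.n_patterns[method]
        return rec


def entropy_report(
    matrix: DayMatrix,
    assignments: Mapping[str, Sequence[int]],
    n_significant: int,
) -> EntropyReport:
    """Full per-user entropy summary for one or more clustering methods."""
    s_bare = bare_entropy(matrix)
    s_clustered, delta, n_pat = {}, {}, {}
    for method, labels in assignments.items():
        s_c = clustered_entropy(matrix, labels)
        s_clustered[method] = s_c
        delta[method] = entropy_drop(s_bare, s_c)
        n_pat[method] = len(np.unique(np.asarray(labels)))
    s_null = null_entropy(modal_probability(matrix), max(n_significant, 1))
    return EntropyReport(
        matrix.user_id, s_bare, s_clustered, delta, s_null, n_pat, n_significant
    )


def entropy_distributions(reports: Sequence[EntropyReport]) -> dict:
    """Empirical CDFs and medians of bare / null / clustered entropies."""
    if len(reports) < 2:
        raise ValueError("need at least 2 users for panel distributions")

    def cdf(values):
        v = np.sort(np.asarray(values, float))
        return {
            "values": v.tolist(),
            "cdf": (np.arange(1, len(v) + 1) / len(v)).tolist(),
            "median": float(np.median(v)),
        }

    out = {
        "s_bare": cdf([r.s_bare for r in reports]),
        "s_null": cdf([r.s_null for r in reports]),
    }
    methods = sorted({m for r in reports for m in r.s_clustered})
    for m in methods:
        vals = [r.s_clustered[m] for r in reports if m in r.s_clustered]
        out[f"s_clustered_{m}"] = cdf(vals)
    return out
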