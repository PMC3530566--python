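"""Location frequency statistics, the 1% significance rule, power-law fits.

Counts are slot-dominance counts (how many slots a location won under the
majority rule), never raw event counts.  Locations rarer than 1% of the
user's most common one are lumped into OTHER, which then behaves as an
ordinary symbol downstream.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import MISSING, OTHER, DayMatrix
from .plfit import PowerLawFit, fit_discrete_power_law


@dataclasses.dataclass
class LocationAlphabet:
    """Ranked slot-dominance table for one user.

    ``entries`` has columns ``location_id``, ``count``, ``freq`` sorted by
    descending count (ties broken by label for determinism); ``significant``
    is the subset with count >= ``threshold_fraction`` of the top count.
    """

    user_id: str
    entries: pd.DataFrame
    significant: list[str]
    threshold_fraction: float = 0.01

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    def rank_of(self) -> dict[str, int]:
        """location_id -> 1-based rank."""
        return {loc: r + 1 for r, loc in enumerate(self.entries["location_id"])}


def location_frequencies(
    matrix: DayMatrix, threshold_fraction: float = 0.01
) -> LocationAlphabet:
    """Rank a user's locations by slot-dominance count.

    MISSING slots are excluded.  Raises if the user has no observed slots.
    """
    labels, counts = np.unique(matrix.slots[matrix.slots != MISSING], return_counts=True)
    if len(labels) == 0:
        raise ValueError(f"user {matrix.user_id}: all slots MISSING")
    order = np.lexsort((labels.astype(str), -counts))
    labels, counts = labels[order], counts[order]
    entries = pd.DataFrame(
        {
            "location_id": labels.astype(str),
            "count": counts.astype(int),
            "freq": counts / counts.sum(),
        }
    )
    cutoff = threshold_fraction * counts[0]
    significant = [
        str(l) for l, c in zip(labels, counts) if c >= cutoff
    ]
    return LocationAlphabet(matrix.user_id, entries, significant, threshold_fraction)


def threshold_locations(
    matrix: DayMatrix, alphabet: LocationAlphabet | None = None
) -> tuple[DayMatrix, LocationAlphabet]:
    """Relabel sub-threshold locations as OTHER; return reduced alphabet."""
    if alphabet is None:
        alphabet = location_frequencies(matrix)
    sig = set(alphabet.significant)
    slots = matrix.slots.copy()
    mask = np.isin(slots, list(sig) + [MISSING], invert=True)
    slots[mask] = OTHER
    out = DayMatrix(matrix.user_id, list(matrix.dates), slots)
    reduced = location_frequencies(out, alphabet.threshold_fraction)
    return out, reduced


def slot_location_counts(matrix: DayMatrix) -> np.ndarray:
    """Distinct non-MISSING labels observed at each slot index."""
    return np.array(
        [
            len({v for v in matrix.slots[:, j] if v != MISSING})
            for j in range(matrix.n_slots)
        ]
    )


def rank_samples(matrix: DayMatrix, alphabet: LocationAlphabet | None = None) -> np.ndarray:
    """Each non-MISSING slot observation mapped to its location's rank."""
    if alphabet is None:
        alphabet = location_frequencies(matrix)
    rank = alphabet.rank_of()
    flat = matrix.slots.ravel()
    return np.array([rank[v] for v in flat if v != MISSING], dtype=np.int64)


def pooled_rank_curve(matrices: Iterable[DayMatrix] | Mapping[str, DayMatrix]) -> pd.DataFrame:
    """Average of per-user normalized rank-frequency curves.

    Mirrors the pooled presentation: every user contributes their own
    normalized curve; ranks beyond a user's alphabet contribute zero.
    Returns columns ``rank`` (1-based) and ``mean_freq``.
    """
    if isinstance(matrices, Mapping):
        matrices = list(matrices.values())
    curves = []
    for dm in matrices:
        curves.append(location_frequencies(dm).entries["freq"].to_numpy())
    if not curves:
        return pd.DataFrame(columns=["rank", "mean_freq"])
    width = max(len(c) for c in curves)
    stack = np.zeros((len(curves), width))
    for i, c in enumerate(curves):
        stack[i, : len(c)] = c
    return pd.DataFrame({"rank": np.arange(1, width + 1), "mean_freq": stack.mean(axis=0)})


def fit_power_law(
    samples, xmin: int | None = None, xmax: int | None = None
) -> PowerLawFit:
    """Discrete MLE power-law fit of rank observations (see :mod:`.plfit`)."""
    return fit_discrete_power_law(samples, xmin=xmin, xmax=xmax)


def panel_rank_samples(matrices: Mapping[str, DayMatrix]) -> np.ndarray:
    """Pooled rank observations across a whole panel."""
    parts = [rank_samples(dm) for dm in matrices.values()]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
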