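"""Core data structures shared by every pipeline stage.

The unit object of the whole analysis is the *day vector*: one calendar day
discretized into ``n_slots`` fixed-length time slots, each carrying a single
location label, the catch-all :data:`OTHER`, or :data:`MISSING`.
"""
from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd

#: Slot label for intervals with no observations.
MISSING = "MISSING"
#: Lump label for locations below the significance threshold.
OTHER = "OTHER"
#: Labels raw traces must not use as location ids.
RESERVED_LABELS = frozenset({MISSING, OTHER})


@dataclasses.dataclass
class DayMatrix:
    """A user's accepted days as an (n_days, n_slots) array of slot labels.

    Parameters
    ----------
    user_id : str
        Identifier of the user the days belong to.
    dates : list of datetime.date
        Calendar date of each row, in chronological order.
    slots : ndarray of object, shape (n_days, n_slots)
        Slot labels; entries are location ids, :data:`OTHER`, or
        :data:`MISSING`.
    """

    user_id: str
    dates: list[datetime.date]
    slots: np.ndarray

    def __post_init__(self) -> None:
        self.slots = np.asarray(self.slots, dtype=object)
        if self.slots.ndim != 2:
            raise ValueError("slots must be a 2-d array (days x slots)")
        if len(self.dates) != self.slots.shape[0]:
            raise ValueError("dates and slots row count differ")
        if any(
            self.dates[i] >= self.dates[i + 1] for i in range(len(self.dates) - 1)
        ):
            raise ValueError("dates must be strictly increasing")

    @property
    def n_days(self) -> int:
        return self.slots.shape[0]

    @property
    def n_slots(self) -> int:
        return self.slots.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of MISSING slots, same shape as ``slots``."""
        return self.slots == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-day fraction of MISSING slots."""
        return self.missing_mask().mean(axis=1)

    def labels(self) -> list[str]:
        """Sorted distinct non-MISSING labels present in the matrix."""
        vals = {v for v in self.slots.ravel() if v != MISSING}
        return sorted(vals)

    def copy(self) -> "DayMatrix":
        return DayMatrix(self.user_id, list(self.dates), self.slots.copy())

    def subset(self, row_idx) -> "DayMatrix":
        """Row-subset preserving chronological order."""
        row_idx = np.asarray(row_idx)
        if row_idx.dtype == bool:
            row_idx = np.flatnonzero(row_idx)
        return DayMatrix(
            self.user_id,
            [self.dates[i] for i in row_idx],
            self.slots[row_idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per day: user_id, date, slot_00..slot_NN."""
        cols = {f"slot_{j:02d}": self.slots[:, j] for j in range(self.n_slots)}
        return pd.DataFrame(
            {"user_id": self.user_id, "date": [d.isoformat() for d in self.dates], **cols}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DayMatrix":
        slot_cols = sorted(c for c in frame.columns if c.startswith("slot_"))
        users = frame["user_id"].unique()
        if len(users) != 1:
            raise ValueError("from_frame expects a single user")
        dates = [datetime.date.fromisoformat(d) for d in frame["date"]]
        return cls(str(users[0]), dates, frame[slot_cols].to_numpy(dtype=object))


def validate_location_id(loc: str) -> str:
    if not loc:
        raise ValueError("location_id must be non-empty")
    if loc in RESERVED_LABELS:
        raise ValueError(f"location_id {loc!r} is a reserved label")
    return loc
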