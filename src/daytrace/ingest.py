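"""Discretize raw timestamped location events into filtered day matrices.

Raw events are (user_id, timestamp, location_id) triplets.  Each calendar
day is cut into half-open slots ``[t, t + slot)``; the slot label is the
location holding the largest dwell time among events observed inside the
slot (earliest-occupied wins ties), MISSING when the slot has no events.
Short MISSING runs flanked by one and the same location are padded, days
with too much residual missing data are dropped, and users with too few
accepted days are rejected.
"""
from __future__ import annotations

import dataclasses
import datetime
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MISSING, DayMatrix

MINUTES_PER_DAY = 24 * 60


@dataclasses.dataclass
class IngestResult:
    """Accepted day matrices plus the exclusion log."""

    matrices: dict[str, DayMatrix]
    excluded_days: dict[str, list[dict]]
    rejected_users: dict[str, int]  # user -> accepted-day count below min_days
    missing_before: float  # missing fraction before padding (accepted users' range)
    missing_after: float  # missing fraction after padding, before day filtering

    def exclusion_log(self) -> dict:
        return {
            "excluded_days": self.excluded_days,
            "rejected_users": self.rejected_users,
            "missing_fraction_before_padding": self.missing_before,
            "missing_fraction_after_padding": self.missing_after,
        }


def _dwell_table(events: pd.DataFrame, slot_minutes: int) -> pd.DataFrame:
    """Per (slot_index, location): total dwell minutes and first-entry time.

    ``events`` holds one user's records sorted by timestamp with columns
    ``timestamp`` (datetime64) and ``location_id``.  An event's span runs to
    the next event or, failing that, indefinitely; spans are clipped to the
    slot containing the event, so coverage never leaks into event-free slots.
    """
    ts = events["timestamp"].to_numpy()
    if len(ts) == 0:
        return pd.DataFrame(columns=["slot_start", "location_id", "dwell", "first_ts"])
    nxt = np.append(ts[1:], np.datetime64("2200-01-01"))  # in-range sentinel
    slot = pd.Series(ts).dt.floor(f"{slot_minutes}min").to_numpy()
    slot_end = slot + np.timedelta64(slot_minutes, "m")
    span_end = np.minimum(nxt, slot_end)
    dwell = (span_end - ts) / np.timedelta64(1, "m")
    tbl = pd.DataFrame(
        {
            "slot_start": slot,
            "location_id": events["location_id"].to_numpy(),
            "dwell": dwell,
            "first_ts": ts,
        }
    )
    return (
        tbl.groupby(["slot_start", "location_id"], as_index=False)
        .agg(dwell=("dwell", "sum"), first_ts=("first_ts", "min"))
    )


def slot_majority(events: pd.DataFrame, slot_minutes: int = 60) -> str:
    """Majority-dwell label for the events of one slot.

    Returns MISSING for an empty frame.  Ties on dwell go to the location
    observed earliest within the slot.
    """
    if len(events) == 0:
        return MISSING
    ev = events.sort_values("timestamp")
    agg = _dwell_table(ev, slot_minutes)
    agg = agg.sort_values(["dwell", "first_ts"], ascending=[False, True], kind="stable")
    return str(agg.iloc[0]["location_id"])


def pad_gaps(sequence: np.ndarray, max_gap_slots: int = 6) -> np.ndarray:
    """Fill short same-flank MISSING runs in a concatenated slot sequence.

    A maximal MISSING run of length <= ``max_gap_slots`` whose two flanking
    labels are equal is filled with that label; every other run (including
    runs touching either end of the record) is untouched.  The input is a
    1-d label array in calendar order; padding may therefore cross midnight.
    """
    seq = np.asarray(sequence, dtype=object).copy()
    n = len(seq)
    i = 0
    while i < n:
        if seq[i] != MISSING:
            i += 1
            continue
        j = i
        while j < n and seq[j] == MISSING:
            j += 1
        run = j - i
        if (
            i > 0
            and j < n
            and run <= max_gap_slots
            and seq[i - 1] == seq[j]
        ):
            seq[i:j] = seq[i - 1]
        i = j
    return seq


def filter_days(
    matrix: DayMatrix, max_missing_fraction: float = 0.30
) -> tuple[DayMatrix, list[dict]]:
    """Keep days whose MISSING fraction is <= the threshold.

    Returns the filtered matrix and an exclusion log (one record per
    dropped day with its date and missing fraction).
    """
    frac = matrix.missing_fraction()
    keep = frac <= max_missing_fraction + 1e-12
    log = [
        {"date": matrix.dates[i].isoformat(), "missing_fraction": float(frac[i])}
        for i in np.flatnonzero(~keep)
    ]
    return matrix.subset(keep), log


def accept_users(
    matrices: Mapping[str, DayMatrix], min_days: int = 30
) -> tuple[dict[str, DayMatrix], dict[str, int]]:
    """Keep users with at least ``min_days`` accepted days."""
    kept, rejected = {}, {}
    for user, dm in matrices.items():
        if dm.n_days >= min_days:
            kept[user] = dm
        else:
            rejected[user] = dm.n_days
    return kept, rejected


def _user_day_matrix(events: pd.DataFrame, slot_minutes: int) -> DayMatrix:
    """Slot one user's sorted events over their full calendar range."""
    n_slots = MINUTES_PER_DAY // slot_minutes
    user = str(events["user_id"].iloc[0])
    agg = _dwell_table(events, slot_minutes)
    agg = agg.sort_values(
        ["slot_start", "dwell", "first_ts"], ascending=[True, False, True], kind="stable"
    )
    winners = agg.drop_duplicates("slot_start", keep="first")

    first_day = events["timestamp"].min().normalize()
    last_day = events["timestamp"].max().normalize()
    n_days = (last_day - first_day).days + 1
    slots = np.full((n_days, n_slots), MISSING, dtype=object)
    delta = (winners["slot_start"] - first_day) / np.timedelta64(slot_minutes, "m")
    flat = delta.to_numpy().astype(np.int64)
    slots.ravel()[flat] = winners["location_id"].astype(str).to_numpy(dtype=object)
    dates = [
        (first_day + pd.Timedelta(days=i)).date() for i in range(n_days)
    ]
    return DayMatrix(user, dates, slots)


def ingest_events(
    events: pd.DataFrame,
    slot_minutes: int = 60,
    max_gap_slots: int = 6,
    max_missing_fraction: float = 0.30,
    min_days: int = 30,
) -> IngestResult:
    """Full ingestion: slot, pad, filter days, accept users.

    Parameters
    ----------
    events : DataFrame
        Columns ``user_id``, ``timestamp`` (parseable to datetime),
        ``location_id``.
    slot_minutes : int
        Slot length; must divide 24 h.
    """
    if MINUTES_PER_DAY % slot_minutes != 0:
        raise ValueError("slot_minutes must divide 24 hours")
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    ev = ev.sort_values(["user_id", "timestamp"], kind="stable")

    raw_missing, padded_missing, total_slots = 0, 0, 0
    per_user: dict[str, DayMatrix] = {}
    excluded: dict[str, list[dict]] = {}
    for user, grp in ev.groupby("user_id", sort=True):
        dm = _user_day_matrix(grp, slot_minutes)
        raw_missing += int(dm.missing_mask().sum())
        total_slots += dm.slots.size
        padded = pad_gaps(dm.slots.ravel(), max_gap_slots).reshape(dm.slots.shape)
        dm = DayMatrix(dm.user_id, dm.dates, padded)
        padded_missing += int(dm.missing_mask().sum())
        dm, log = filter_days(dm, max_missing_fraction)
        per_user[str(user)] = dm
        if log:
            excluded[str(user)] = log

    kept, rejected = accept_users(per_user, min_days)
    return IngestResult(
        matrices=kept,
        excluded_days=excluded,
        rejected_users=rejected,
        missing_before=raw_missing / total_slots if total_slots else 0.0,
        missing_after=padded_missing / total_slots if total_slots else 0.0,
    )


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str, "location_id": str})
    missing = {"user_id", "timestamp", "location_id"} - set(df.columns)
    if missing:
        raise ValueError(f"event file lacks columns: {sorted(missing)}")
    return df


def write_day_matrices(matrices: Mapping[str, DayMatrix], path) -> None:
    """All users' accepted days as one CSV (row = day, column = slot)."""
    frames = [dm.to_frame() for dm in matrices.values()]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["user_id", "date"]
    )
    out.to_csv(path, index=False)


def read_day_matrices(path) -> dict[str, DayMatrix]:
    df = pd.read_csv(path, dtype=str)
    return {
        str(u): DayMatrix.from_frame(g) for u, g in df.groupby("user_id", sort=True)
    }
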