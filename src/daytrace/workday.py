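"""Working-day identification and the two-hazard departure model.

The departure model is a discrete-time survival construction: the per-step
probability of finally leaving work grows exponentially on both sides of a
typical day length T0 — one rate for leaving early, another for not
staying longer — sharing a baseline hazard h0 at T0:

    h(t) = h0 * exp(a_early * (t - T0))   for t <= T0
    h(t) = h0 * exp(a_late  * (t - T0))   for t >  T0
    pdf(t) = h(t) * prod_{s < t} (1 - h(s)),  h clipped to <= 1,

normalized over the evaluation grid.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import MISSING, OTHER, DayMatrix


@dataclasses.dataclass
class DepartureModel:
    t0: float
    a_early: float
    a_late: float
    h0: float = 0.1

    def __post_init__(self) -> None:
        if self.a_early <= 0 or self.a_late <= 0:
            raise ValueError("hazard growth rates must be positive")
        if not 0 < self.h0 <= 1:
            raise ValueError("h0 must lie in (0, 1]")

    def hazard(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        rate = np.where(t <= self.t0, self.a_early, self.a_late)
        return np.minimum(self.h0 * np.exp(rate * (t - self.t0)), 1.0)


def departure_pdf(model: DepartureModel, grid) -> np.ndarray:
    """Normalized leave-time distribution over an increasing grid."""
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    h = model.hazard(grid)
    if h[0] >= 1.0:
        warnings.warn("hazard saturates at the grid start", stacklevel=2)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - h)[:-1]])
    pdf = h * surv
    total = pdf.sum()
    if total <= 0:
        raise ValueError("degenerate pdf on this grid")
    return pdf / total


def sample_departure_times(
    model: DepartureModel, grid, size: int, rng
) -> np.ndarray:
    """Simulate leave times by sequential per-step Bernoulli hazards.

    A trajectory surviving past the grid end is resampled, which makes the
    sampler exactly consistent with the grid-normalized analytic pdf.
    """
    grid = np.asarray(grid, float)
    h = model.hazard(grid)
    out = np.empty(size)
    filled = 0
    while filled < size:
        batch = max(size - filled, 1)
        u = rng.random((batch, len(grid)))
        leave = u < h[None, :]
        any_leave = leave.any(axis=1)
        first = np.argmax(leave, axis=1)
        good = grid[first[any_leave]]
        take = min(len(good), size - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# work location and day lengths


def _home_location(matrix: DayMatrix, night_slots=range(0, 7)) -> str | None:
    vals = matrix.slots[:, list(night_slots)].ravel()
    vals = vals[(vals != MISSING) & (vals != OTHER)]
    if len(vals) == 0:
        return None
    labs, counts = np.unique(vals.astype(str), return_counts=True)
    order = np.lexsort((labs, -counts))
    return str(labs[order[0]])


def _max_consecutive(row: np.ndarray, loc: str) -> int:
    best = run = 0
    for v in row:
        run = run + 1 if v == loc else 0
        best = max(best, run)
    return best


def find_work_location(
    matrix: DayMatrix,
    assignment=None,  # accepted for interface symmetry; not required
    day_window: tuple[int, int] = (9, 17),
    min_workdays: int = 20,
    min_consecutive: int = 4,
) -> str | None:
    """Most-occupied non-home daytime location, if it qualifies.

    A user counts as a regular worker only when the candidate location
    appears on at least ``min_workdays`` days with ``min_consecutive`` or
    more consecutive slots; otherwise None.
    """
    home = _home_location(matrix)
    lo, hi = day_window
    block = matrix.slots[:, lo:hi].ravel()
    block = block[(block != MISSING) & (block != OTHER)]
    if home is not None:
        block = block[block != home]
    if len(block) == 0:
        return None
    labs, counts = np.unique(block.astype(str), return_counts=True)
    order = np.lexsort((labs, -counts))
    candidate = str(labs[order[0]])
    qualifying = sum(
        1
        for d in range(matrix.n_days)
        if _max_consecutive(matrix.slots[d], candidate) >= min_consecutive
    )
    return candidate if qualifying >= min_workdays else None


def day_lengths(
    matrix: DayMatrix, work_location: str, min_workdays: int = 20
) -> pd.DataFrame:
    """Per working day: arrival slot, departure slot, length, z-scored length.

    Length is last-to-first occupancy of the work location (lunch breaks
    elsewhere do not split the day).  Raises when fewer than
    ``min_workdays`` working days remain.
    """
    rows = []
    for d in range(matrix.n_days):
        idx = np.flatnonzero(matrix.slots[d] == work_location)
        if len(idx) == 0:
            continue
        first, last = int(idx[0]), int(idx[-1])
        rows.append(
            {
                "user_id": matrix.user_id,
                "date": matrix.dates[d].isoformat(),
                "arrival_slot": first,
                "departure_slot": last,
                "length": last - first + 1,
            }
        )
    if len(rows) < min_workdays:
        raise ValueError(
            f"user {matrix.user_id}: only {len(rows)} working days "
            f"(< {min_workdays})"
        )
    table = pd.DataFrame(rows)
    lengths = table["length"].to_numpy(float)
    sd = lengths.std()  # population sd so pooled z has unit variance
    table["z_length"] = 0.0 if sd == 0 else (lengths - lengths.mean()) / sd
    return table


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclasses.dataclass
class DepartureFit:
    model: DepartureModel
    se: dict[str, float]
    ks: float
    log_likelihood: float
    n: int
    grid: np.ndarray
    converged: bool


def _nll(theta: np.ndarray, grid: np.ndarray, counts: np.ndarray) -> float:
    log_h0, t0, log_ae, log_al = theta
    h0 = np.exp(log_h0)
    if h0 > 1.0:
        return np.inf
    model = DepartureModel(t0, np.exp(log_ae), np.exp(log_al), h0)
    pdf = np.clip(departure_pdf(model, grid), 1e-300, None)
    return float(-(counts * np.log(pdf)).sum())


def _hessian(fun, x, eps=1e-4):
    n = len(x)
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            h[i, j] = h[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * eps**2)
    return h


def fit_departure_model(
    lengths: Sequence[float],
    grid: np.ndarray | None = None,
    min_n: int = 100,
) -> DepartureFit:
    """MLE of (h0, T0, a_early, a_late) on pooled day lengths.

    Lengths are binned onto ``grid`` (default: unit steps spanning the
    data).  Standard errors come from the observed information; the KS
    statistic compares the empirical and fitted CDFs on the grid.
    """
    x = np.asarray(lengths, float)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pooled lengths, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all lengths equal")
    if grid is None:
        grid = np.arange(np.floor(x.min()), np.ceil(x.max()) + 1.0)
    grid = np.asarray(grid, float)
    idx = np.clip(np.searchsorted(grid, x - 1e-9), 0, len(grid) - 1)
    counts = np.bincount(idx, minlength=len(grid)).astype(float)

    t0_init = grid[np.argmax(counts)]
    best = None
    for h0_init, a_init in [(0.1, 0.1), (0.3, 0.05), (0.05, 0.3)]:
        theta0 = np.array([np.log(h0_init), t0_init, np.log(a_init), np.log(a_init)])
        res = optimize.minimize(
            _nll,
            theta0,
            args=(grid, counts),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("departure-model fit did not converge")

    log_h0, t0, log_ae, log_al = best.x
    model = DepartureModel(float(t0), float(np.exp(log_ae)), float(np.exp(log_al)), float(np.exp(log_h0)))

    hess = _hessian(lambda th: _nll(th, grid, counts), best.x)
    se = {k: float("nan") for k in ("h0", "t0", "a_early", "a_late")}
    try:
        cov = np.linalg.inv(hess)
        d = np.sqrt(np.clip(np.diag(cov), 0, None))
        # delta method back to natural units for the log-parametrized entries
        se = {
            "h0": float(d[0] * model.h0),
            "t0": float(d[1]),
            "a_early": float(d[2] * model.a_early),
            "a_late": float(d[3] * model.a_late),
        }
    except np.linalg.LinAlgError:
        pass

    pdf = departure_pdf(model, grid)
    ecdf = np.cumsum(counts) / counts.sum()
    ks = float(np.max(np.abs(ecdf - np.cumsum(pdf))))
    return DepartureFit(
        model=model,
        se=se,
        ks=ks,
        log_likelihood=float(-best.fun),
        n=len(x),
        grid=grid,
        converged=bool(best.success),
    )
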