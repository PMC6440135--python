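"""30-minute census grid: aggregation, queue recursion, shift labels, design table.

The ED day is divided into three 8-hour work shifts starting at 07:00
(day 07–15, evening 15–23, night 23–07). Arrival and departure events are
binned onto a half-open 30-minute grid; the queue (number of patients
present at the start of each interval) follows the recursion

    Q(t+1) = Q(t) + A(t) - D(t),   Q(0) = 0.

The design table turns the census into one binomial observation per
interval s: response D(s) out of n(s) = Q(s) + A(s) trials, with
covariates A(s), Q(s-1), Q(s)-Q(s-1), the departure counts of the three
preceding intervals, and shift/weekend indicators with their interaction.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventRecord, events_to_frame

INTERVAL = timedelta(minutes=30)
SHIFT_LEVELS = ("day", "evening", "night")

#: Covariate order of the design table (mirrors the reporting order of the
#: odds-ratio table: arrivals, queue terms, departure lags, shift, weekend,
#: shift-by-weekend interaction).
DESIGN_COVARIATES = (
    "arrivals",
    "dqueue",
    "queue_prev",
    "dep_lag1",
    "dep_lag2",
    "dep_lag3",
    "shift_evening",
    "shift_night",
    "weekend",
    "evening_weekend",
    "night_weekend",
)


def _check_half_hour(ts: datetime, name: str) -> None:
    if ts.minute % 30 or ts.second or ts.microsecond:
        raise ValueError(f"{name} must fall on a half-hour boundary, got {ts}")


def make_grid(grid_start: datetime, grid_end: datetime) -> pd.DatetimeIndex:
    """Half-hour interval start times covering [grid_start, grid_end)."""
    _check_half_hour(grid_start, "grid_start")
    _check_half_hour(grid_end, "grid_end")
    if grid_start >= grid_end:
        raise ValueError("grid_start must precede grid_end")
    return pd.date_range(grid_start, grid_end, freq="30min", inclusive="left")


def aggregate(
    events: Sequence[EventRecord] | pd.DataFrame,
    grid_start: datetime,
    grid_end: datetime,
) -> pd.DataFrame:
    """Bin arrivals and departures onto the 30-minute grid.

    An event whose arrival (departure) falls in the half-open window
    [start, start + 30 min) increments that interval's arrival (departure)
    count; events outside [grid_start, grid_end) are ignored.
    """
    grid = make_grid(grid_start, grid_end)
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(list(events))
    n = len(grid)
    arrivals = np.zeros(n, dtype=int)
    departures = np.zeros(n, dtype=int)
    if len(frame):
        for col, counts in (("arrival", arrivals), ("departure", departures)):
            ts = pd.to_datetime(frame[col])
            inside = (ts >= grid_start) & (ts < grid_end)
            idx = (
                (ts[inside] - grid_start) // INTERVAL
            ).astype(int)
            np.add.at(counts, idx.to_numpy(), 1)
    return pd.DataFrame({"start": grid, "arrivals": arrivals, "departures": departures})


def compute_queue(census: pd.DataFrame, q0: int = 0) -> pd.DataFrame:
    """Fill the queue column by the recursion Q(t+1) = Q(t) + A(t) - D(t).

    Intervals where the departures exceed the available patients
    (D(t) > Q(t) + A(t), possible when patients present before the grid
    start depart in-grid) are flagged ``valid=False`` and the queue is
    floored at zero afterwards; they are excluded from model fitting but
    kept in the series.
    """
    a = census["arrivals"].to_numpy()
    d = census["departures"].to_numpy()
    n = len(census)
    q = np.zeros(n, dtype=int)
    valid = np.ones(n, dtype=bool)
    cur = int(q0)
    for t in range(n):
        q[t] = cur
        if d[t] > cur + a[t]:
            valid[t] = False
        cur = max(cur + a[t] - d[t], 0)
    out = census.copy()
    out["queue"] = q
    out["valid"] = valid
    return out


def label(census: pd.DataFrame) -> pd.DataFrame:
    """Attach work-shift and weekend labels to each interval.

    Shift: day for start hours [7, 15), evening [15, 23), night otherwise.
    Weekend: start in [Friday 23:00, Sunday 23:00) — Friday and Saturday
    night shifts belong to the weekend, Sunday night does not.
    """
    start = pd.to_datetime(census["start"])
    hour = start.dt.hour
    shift = np.where(
        (hour >= 7) & (hour < 15), "day", np.where((hour >= 15) & (hour < 23), "evening", "night")
    )
    dow = start.dt.dayofweek  # Monday=0 .. Sunday=6
    weekend = ((dow == 4) & (hour >= 23)) | (dow == 5) | ((dow == 6) & (hour < 23))
    out = census.copy()
    out["shift"] = shift
    out["weekend"] = weekend.to_numpy()
    return out


def census_from_events(
    events: Sequence[EventRecord] | pd.DataFrame,
    grid_start: datetime,
    grid_end: datetime,
    q0: int = 0,
) -> pd.DataFrame:
    """Aggregate, run the queue recursion and label in one step."""
    return label(compute_queue(aggregate(events, grid_start, grid_end), q0=q0))


def _shift_exclusion_cutoff(grid_start: datetime) -> datetime:
    """End of the third work shift after the grid start.

    Shift boundaries fall at 07:00, 15:00 and 23:00. All intervals starting
    before the third boundary strictly after ``grid_start`` are dropped,
    which removes the first three (possibly partial) shifts and with them
    the influence of the arbitrary Q(0) = 0.
    """
    boundary_hours = (7, 15, 23)
    ts = grid_start.replace(minute=0, second=0, microsecond=0)
    ts = ts.replace(hour=0)
    count = 0
    while True:
        for h in boundary_hours:
            cand = ts.replace(hour=h)
            if cand > grid_start:
                count += 1
                if count == 3:
                    return cand
        ts += timedelta(days=1)


def build_design(
    census: pd.DataFrame,
    n_lags: int = 3,
    arrival_lag: bool = False,
) -> pd.DataFrame:
    """Assemble the model design table from a labelled census series.

    One row per retained interval s carrying the response ``D`` (departures),
    the trial count ``n = Q(s) + A(s)`` and the covariates listed in
    :data:`DESIGN_COVARIATES`. Rows are dropped when

    * s starts within the first three work shifts of the grid,
    * any required departure lag reaches before the grid,
    * n = 0 (no patient could depart), or
    * the interval was flagged invalid by the queue recursion.

    ``arrival_lag=True`` replaces the concurrent arrival count A(s) with
    A(s-1), the alternative reading of the arrival covariate.
    """
    required = {"start", "arrivals", "departures", "queue", "shift", "weekend"}
    missing = required - set(census.columns)
    if missing:
        raise ValueError(f"census lacks columns {sorted(missing)}")
    start = pd.to_datetime(census["start"])
    grid_start = start.iloc[0].to_pydatetime()
    cutoff = _shift_exclusion_cutoff(grid_start)
    if start.iloc[-1].to_pydatetime() < cutoff:
        raise ValueError(
            "census series ends before the three-shift start-up exclusion window"
        )

    a = census["arrivals"].to_numpy()
    d = census["departures"].to_numpy()
    q = census["queue"].to_numpy()
    valid = census["valid"].to_numpy() if "valid" in census.columns else np.ones(len(a), bool)

    df = pd.DataFrame({"start": start})
    df["D"] = d
    x_arr = np.roll(a, 1) if arrival_lag else a
    df["n"] = q + a
    df["arrivals"] = x_arr
    df["queue_prev"] = np.roll(q, 1)
    df["dqueue"] = q - np.roll(q, 1)
    for lag in range(1, n_lags + 1):
        df[f"dep_lag{lag}"] = np.roll(d, lag)
    evening = (census["shift"] == "evening").to_numpy().astype(int)
    night = (census["shift"] == "night").to_numpy().astype(int)
    weekend = census["weekend"].to_numpy().astype(int)
    df["shift_evening"] = evening
    df["shift_night"] = night
    df["weekend"] = weekend
    df["evening_weekend"] = evening * weekend
    df["night_weekend"] = night * weekend

    max_lag = max(n_lags, 1 if arrival_lag else 0, 1)  # queue_prev/dqueue need one lag
    keep = np.ones(len(df), dtype=bool)
    keep[:max_lag] = False  # np.roll wraps; these lags are undefined
    keep &= (start >= cutoff).to_numpy()
    keep &= df["n"].to_numpy() > 0
    keep &= valid
    out = df.loc[keep].reset_index(drop=True)
    out.attrs["n_excluded"] = int(len(df) - len(out))
    out.attrs["n_lags"] = n_lags
    return out
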