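"""Event-level and census-level CSV I/O with strict validation.

The raw input is one row per ED visit: an opaque visit id, an arrival
timestamp and a departure timestamp, both naive local ISO-8601 times.
Malformed rows are never dropped silently; every violation raises with
the offending row or column named.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

EVENT_COLUMNS = ("visit_id", "arrival", "departure")
CENSUS_COLUMNS = ("interval_start", "arrivals", "departures", "queue_start", "shift", "weekend")

#: ISO-8601 without timezone offset; seconds optional on input.
_TS_FORMATS = ("%Y-%m-%dT%H:%M:%S", "%Y-%m-%dT%H:%M")


class EventValidationError(ValueError):
    """A row or column of an events file violates the schema."""


@dataclass(frozen=True)
class EventRecord:
    """One patient visit: arrival and departure timestamps (naive local)."""

    visit_id: str
    arrival: datetime
    departure: datetime

    def __post_init__(self) -> None:
        if self.departure < self.arrival:
            raise EventValidationError(
                f"departure before arrival for visit {self.visit_id!r}"
            )


def parse_timestamp(text: str) -> datetime:
    """Parse a naive local ISO-8601 timestamp (minute or second resolution)."""
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise EventValidationError(f"unparseable timestamp {text!r}")


def format_timestamp(ts: datetime) -> str:
    """Render a timestamp as ISO-8601, dropping a zero seconds field."""
    if ts.second or ts.microsecond:
        return ts.strftime("%Y-%m-%dT%H:%M:%S")
    return ts.strftime("%Y-%m-%dT%H:%M")


def read_events(path: str | Path) -> list[EventRecord]:
    """Read an events CSV (columns visit_id, arrival, departure).

    Records are returned in file order. Any unparseable timestamp or a
    departure preceding its arrival raises :class:`EventValidationError`
    naming the 1-based data row.
    """
    path = Path(path)
    records: list[EventRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in EVENT_COLUMNS:
            if col not in header:
                raise EventValidationError(f"missing column {col!r} in {path}")
        for i, row in enumerate(reader, start=1):
            try:
                arrival = parse_timestamp(row["arrival"])
                departure = parse_timestamp(row["departure"])
            except EventValidationError as exc:
                raise EventValidationError(f"{exc}, row {i}") from None
            if departure < arrival:
                raise EventValidationError(f"departure before arrival, row {i}")
            records.append(EventRecord(row["visit_id"], arrival, departure))
    return records


def write_events(records: Iterable[EventRecord], path: str | Path) -> None:
    """Write events to CSV with header ``visit_id,arrival,departure``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.visit_id, format_timestamp(rec.arrival), format_timestamp(rec.departure)]
            )


def events_to_frame(records: Sequence[EventRecord]) -> pd.DataFrame:
    """Convert event records to a DataFrame with datetime columns."""
    return pd.DataFrame(
        {
            "visit_id": [r.visit_id for r in records],
            "arrival": pd.to_datetime([r.arrival for r in records]),
            "departure": pd.to_datetime([r.departure for r in records]),
        }
    )


def read_census(path: str | Path) -> pd.DataFrame:
    """Read a census CSV written by :func:`write_census`.

    Columns: interval_start, arrivals, departures, queue_start, shift, weekend.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in CENSUS_COLUMNS:
        if col not in df.columns:
            raise EventValidationError(f"missing column {col!r} in {path}")
    out = pd.DataFrame(
        {
            "start": pd.to_datetime(df["interval_start"]),
            "arrivals": df["arrivals"].astype(int),
            "departures": df["departures"].astype(int),
            "queue": df["queue_start"].astype(int),
            "shift": df["shift"].astype(str),
            "weekend": df["weekend"].astype(bool),
        }
    )
    if "valid" in df.columns:
        out["valid"] = df["valid"].astype(bool)
    return out


def write_census(census: pd.DataFrame, path: str | Path) -> None:
    """Write a census frame (columns start/arrivals/departures/queue/shift/weekend)."""
    out = pd.DataFrame(
        {
            "interval_start": census["start"].map(format_timestamp),
            "arrivals": census["arrivals"].astype(int),
            "departures": census["departures"].astype(int),
            "queue_start": census["queue"].astype(int),
            "shift": census["shift"],
            "weekend": census["weekend"].astype(bool),
        }
    )
    if "valid" in census.columns:
        out["valid"] = census["valid"].astype(bool)
    out.to_csv(path, index=False)
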