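"""Event-catalog I/O, validation, and spatial windowing.

A catalog is a chronologically sorted set of point events (crashes) on a
continuous time axis measured in days since a calendar origin.  All other
modules consume :class:`EventCatalog`; this module owns the conventions:

* time unit is **days** (fractional), the origin is midnight local time of
  the first event's date unless given explicitly;
* coordinates, when present, are WGS84 decimal degrees and distances are
  great-circle (haversine) miles on a sphere of radius 3958.8 mi;
* tied timestamps are kept and nudged apart by 1 second in input order so
  the times are strictly increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

EARTH_RADIUS_MILES = 3958.8
#: 1 second expressed in days; used to break tied timestamps.
TIE_EPS_DAYS = 1.0 / 86400.0

_DATE_FORMATS = ("%Y-%m-%d", "%m/%d/%Y", "%Y/%m/%d")
_TIME_FORMATS = ("%H:%M", "%H:%M:%S")
_DATETIME_FORMATS = ("%Y-%m-%d %H:%M", "%Y-%m-%d %H:%M:%S",
                     "%m/%d/%Y %H:%M", "%m/%d/%Y %H:%M:%S",
                     "%Y-%m-%dT%H:%M", "%Y-%m-%dT%H:%M:%S")


class CatalogError(ValueError):
    """Catalog-level input problem (empty file, missing columns, ...)."""


class CatalogParseError(CatalogError):
    """A record failed to parse; carries the offending 0-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass
class EventRecord:
    """A single source event: calendar timestamp plus optional geography.

    ``attributes`` carries free-form columns (weather, severity, ...) that
    the point-process model never looks at.
    """

    timestamp: datetime
    longitude: float | None = None
    latitude: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise CatalogError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise CatalogError(f"longitude {self.longitude} outside [-180, 180]")

    @property
    def has_coordinates(self) -> bool:
        return self.longitude is not None and self.latitude is not None


@dataclass
class EventCatalog:
    """Sorted event times on a continuous day axis over ``[0, window_end]``.

    Parameters
    ----------
    times
        Event times in days since ``origin``, nondecreasing, within the
        observation window.
    origin
        Calendar date-time of ``t = 0``.
    window_end
        Length ``T`` of the observation window in days.
    records
        Optional source records, one per event, in the same order.
    """

    times: np.ndarray
    origin: datetime
    window_end: float
    records: list[EventRecord] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise CatalogError("times must be one-dimensional")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise CatalogError("times must be nondecreasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.window_end):
            raise CatalogError("times must lie within [0, window_end]")
        if self.records is not None and len(self.records) != self.times.size:
            raise CatalogError("records length must match times length")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def origin_weekday(self) -> int:
        """Weekday of the origin, Monday = 0 ... Sunday = 6."""
        return self.origin.weekday()

    @property
    def has_coordinates(self) -> bool:
        return self.records is not None and all(r.has_coordinates for r in self.records)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (longitude, latitude) arrays; error if any are missing."""
        if self.records is None:
            raise CatalogError("catalog carries no source records")
        missing = [i for i, r in enumerate(self.records) if not r.has_coordinates]
        if missing:
            raise CatalogError(f"events missing coordinates at rows {missing}")
        lon = np.array([r.longitude for r in self.records], dtype=float)
        lat = np.array([r.latitude for r in self.records], dtype=float)
        return lon, lat

    def timestamps(self) -> list[datetime]:
        """Calendar timestamps reconstructed from the day axis."""
        return [self.origin + timedelta(days=float(t)) for t in self.times]

    def subset(self, mask: np.ndarray) -> "EventCatalog":
        """Sub-catalog of events selected by a boolean mask; window unchanged."""
        mask = np.asarray(mask, dtype=bool)
        recs = None
        if self.records is not None:
            recs = [r for r, m in zip(self.records, mask) if m]
        return EventCatalog(self.times[mask], self.origin, self.window_end, recs)


def _try_parse(text: str, formats) -> datetime | None:
    for fmt in formats:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    return None


def _parse_timestamp(date_text: str, time_text: str | None, row: int) -> datetime:
    date_text = str(date_text).strip()
    if time_text is None:
        ts = _try_parse(date_text, _DATETIME_FORMATS + _DATE_FORMATS)
        if ts is None:
            raise CatalogParseError(row, f"unparseable date-time {date_text!r}")
        return ts
    d = _try_parse(date_text, _DATE_FORMATS)
    if d is None:
        raise CatalogParseError(row, f"unparseable date {date_text!r}")
    t = _try_parse(str(time_text).strip(), _TIME_FORMATS)
    if t is None:
        raise CatalogParseError(row, f"unparseable time {time_text!r}")
    return d.replace(hour=t.hour, minute=t.minute, second=t.second)


def _break_ties(times: np.ndarray) -> np.ndarray:
    """Make nondecreasing times strictly increasing by +1 s nudges."""
    out = times.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + TIE_EPS_DAYS
    return out


def load_catalog(path,
                 date_column: str = "crash_date",
                 time_column: str | None = "crash_time",
                 lon_column: str = "longitude",
                 lat_column: str = "latitude",
                 origin: datetime | None = None,
                 window_end: float | None = None) -> EventCatalog:
    """Read a crash-report CSV export into an :class:`EventCatalog`.

    The CSV must carry a date column and (optionally) a separate time
    column; ISO-8601 and US ``MM/DD/YYYY`` dates plus ``HH:MM[:SS]`` times
    are accepted.  Coordinate columns are optional.  Events are sorted
    ascending in time; the origin defaults to midnight of the earliest
    event's date and the window ends at midnight after the last event.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise CatalogError(f"{path}: no event rows")
    if date_column not in df.columns:
        raise CatalogError(f"{path}: missing date column {date_column!r}")
    if time_column is not None and time_column not in df.columns:
        time_column = None

    special = {date_column, time_column, lon_column, lat_column}
    attr_cols = [c for c in df.columns if c not in special]

    records: list[EventRecord] = []
    for row, rec in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, rec))
        date_text = rec[date_column]
        if date_text is None or (isinstance(date_text, float) and math.isnan(date_text)):
            raise CatalogParseError(row, "missing date")
        ts = _parse_timestamp(date_text, rec.get(time_column) if time_column else None, row)

        def _coord(col):
            v = rec.get(col)
            if v is None or str(v).strip() in ("", "nan"):
                return None
            try:
                return float(v)
            except ValueError:
                raise CatalogParseError(row, f"bad coordinate {v!r} in {col}") from None

        attrs = {c: rec[c] for c in attr_cols if rec[c] is not None and str(rec[c]) != "nan"}
        records.append(EventRecord(ts, _coord(lon_column), _coord(lat_column), attrs))

    order = sorted(range(len(records)), key=lambda i: records[i].timestamp)
    records = [records[i] for i in order]

    if origin is None:
        first = records[0].timestamp
        origin = datetime(first.year, first.month, first.day)
    times = np.array([(r.timestamp - origin).total_seconds() / 86400.0 for r in records])
    if times[0] < 0:
        raise CatalogError("origin is later than the earliest event")
    times = _break_ties(times)

    if window_end is None:
        last = records[-1].timestamp
        day_after = datetime(last.year, last.month, last.day) + timedelta(days=1)
        window_end = (day_after - origin).total_seconds() / 86400.0
    window_end = max(float(window_end), float(times[-1]))
    return EventCatalog(times, origin, window_end, records)


def write_catalog(catalog: EventCatalog, path) -> None:
    """Write a catalog as CSV with date/time/coordinate columns + ``t_days``."""
    if catalog.records is None:
        stamps = catalog.timestamps()
        lons = [None] * catalog.n
        lats = [None] * catalog.n
    else:
        stamps = [r.timestamp for r in catalog.records]
        lons = [r.longitude for r in catalog.records]
        lats = [r.latitude for r in catalog.records]
    df = pd.DataFrame({
        "crash_date": [s.strftime("%Y-%m-%d") for s in stamps],
        "crash_time": [s.strftime("%H:%M:%S" if s.second else "%H:%M") for s in stamps],
        "longitude": lons,
        "latitude": lats,
        "t_days": catalog.times,
    })
    df.to_csv(path, index=False)


def haversine_miles(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in miles between WGS84 points (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_MILES * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def filter_corridor(catalog: EventCatalog, center: tuple[float, float],
                    radius_miles: float) -> EventCatalog:
    """Keep events within ``radius_miles`` great-circle miles of ``center``.

    ``center`` is ``(longitude, latitude)``.  The time axis, origin and
    window are unchanged, so intensities remain comparable across filters.
    """
    lon, lat = catalog.coordinates()
    dist = haversine_miles(lon, lat, center[0], center[1])
    return catalog.subset(dist <= radius_miles)


def _polyline_segments(polyline):
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise CatalogError("polyline must be a sequence of >= 2 (lon, lat) points")
    seg = haversine_miles(pts[:-1, 0], pts[:-1, 1], pts[1:, 0], pts[1:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, cum


def polyline_length_miles(polyline) -> float:
    """Total haversine length of a (lon, lat) polyline in miles."""
    _, cum = _polyline_segments(polyline)
    return float(cum[-1])


def point_along(polyline, offset_miles: float) -> tuple[float, float]:
    """(lon, lat) of the point ``offset_miles`` along the polyline.

    Interpolation is linear in lon/lat within a segment — a straight-corridor
    approximation adequate at highway scales.
    """
    pts, cum = _polyline_segments(polyline)
    if offset_miles < -1e-9 or offset_miles > cum[-1] + 1e-9:
        raise CatalogError(f"offset {offset_miles} outside polyline length {cum[-1]:.3f}")
    offset = min(max(offset_miles, 0.0), cum[-1])
    k = int(np.searchsorted(cum, offset, side="right") - 1)
    k = min(k, len(cum) - 2)
    seg_len = cum[k + 1] - cum[k]
    frac = 0.0 if seg_len == 0 else (offset - cum[k]) / seg_len
    lon = pts[k, 0] + frac * (pts[k + 1, 0] - pts[k, 0])
    lat = pts[k, 1] + frac * (pts[k + 1, 1] - pts[k, 1])
    return float(lon), float(lat)


def window_offsets(extent_miles: float, step_miles: float) -> np.ndarray:
    """Window-center offsets 0, step, 2·step, ..., extent (inclusive)."""
    if step_miles <= 0:
        raise CatalogError("step must be positive")
    if extent_miles < 0:
        raise CatalogError("extent must be nonnegative")
    n = int(round(extent_miles / step_miles))
    offs = np.arange(n + 1) * step_miles
    # guard against float drift when extent is not a multiple of step
    if offs[-1] > extent_miles + 1e-9:
        offs = offs[:-1]
    elif extent_miles - offs[-1] > 1e-9:
        offs = np.append(offs, extent_miles)
    return offs


def sliding_windows(catalog: EventCatalog, polyline,
                    extent_miles: float, step_miles: float,
                    radius_miles: float = 2.0) -> list[EventCatalog]:
    """Corridor scan: one circular window per offset along the polyline.

    Window centers advance by ``step_miles`` from the start of the polyline
    over ``extent_miles`` (endpoints included); each window keeps events
    within ``radius_miles`` of its center, exactly as
    :func:`filter_corridor` does.
    """
    if polyline_length_miles(polyline) + 1e-9 < extent_miles:
        raise CatalogError("polyline is shorter than the requested extent")
    out = []
    for off in window_offsets(extent_miles, step_miles):
        center = point_along(polyline, float(off))
        out.append(filter_corridor(catalog, center, radius_miles))
    return out
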