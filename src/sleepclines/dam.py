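"""Reading and writing Drosophila Activity Monitor (DAM) data.

Trikinetics DAM monitors record infrared beam crosses per fly in 1-minute
bins.  The DAMSystem text format is tab-delimited with one row per reading:
a running index, date, time, a status code, a block of metadata columns and
32 channel counts (the common 42-column layout; column positions are
configurable through :class:`DamLayout`).

All downstream analysis is phrased in Zeitgeber time (ZT): hours since
lights-on, with ZT00 = lights-on and, under a 12:12 cycle, ZT12 = lights-off.
A "day" here always means a full ZT00 -> ZT24 span.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

__all__ = [
    "LightSchedule",
    "BeamCrossSeries",
    "SampleSheet",
    "DamLayout",
    "DamParseError",
    "read_dam_monitor_file",
    "write_dam_monitor_file",
    "read_long_csv",
    "slice_experiment_days",
    "drop_gap_days",
    "write_phenotype_table",
]


class DamParseError(ValueError):
    """Raised when a monitor file cannot be parsed."""


@dataclass(frozen=True)
class LightSchedule:
    """A rectangular light/dark cycle in local clock time.

    Parameters
    ----------
    lights_on_clock_time
        Time of day at which lights switch on (= ZT00).
    photophase_hours, scotophase_hours
        Durations of the lights-on and lights-off half-cycles; must sum
        to 24 h.
    temperature_profile
        Optional ``[(zt_hour, deg_C), ...]`` description of the thermal
        program; carried as metadata only.
    """

    lights_on_clock_time: dt.time = dt.time(8, 0)
    photophase_hours: float = 12.0
    scotophase_hours: float = 12.0
    temperature_profile: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if abs(self.photophase_hours + self.scotophase_hours - 24.0) > 1e-9:
            raise ValueError("photophase_hours + scotophase_hours must equal 24")

    @property
    def photophase_minutes(self) -> int:
        return int(round(self.photophase_hours * 60))

    def zt_minute_of(self, timestamp: dt.datetime) -> int:
        """Minute-of-cycle (0..1439) of ``timestamp``; 0 = lights-on."""
        on = timestamp.replace(
            hour=self.lights_on_clock_time.hour,
            minute=self.lights_on_clock_time.minute,
            second=0,
            microsecond=0,
        )
        delta = int((timestamp - on).total_seconds() // 60)
        return delta % MINUTES_PER_DAY


@dataclass
class BeamCrossSeries:
    """One fly's per-minute beam-cross counts, ZT-aligned via its schedule.

    ``counts[i]`` is the number of beam crosses in the minute starting at
    ``start_timestamp + i minutes``.  ``gap_mask[i]`` is True where the
    monitor reading was missing or flagged not-OK and the count was filled
    by policy.
    """

    fly_id: str
    counts: np.ndarray
    schedule: LightSchedule = field(default_factory=LightSchedule)
    start_timestamp: dt.datetime = dt.datetime(2011, 9, 1, 8, 0)
    line_id: str = ""
    population_id: str = ""
    latitude: float = float("nan")
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gap_mask is not None:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != self.counts.shape:
                raise ValueError("gap_mask must match counts in length")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def start_zt_minute(self) -> int:
        return self.schedule.zt_minute_of(self.start_timestamp)

    def zt_minutes(self) -> np.ndarray:
        """ZT minute-of-day (0..1439) for every sample."""
        return (self.start_zt_minute + np.arange(len(self.counts))) % MINUTES_PER_DAY

    def phase_labels(self) -> np.ndarray:
        """Per-minute phase: True where photophase (lights on)."""
        return self.zt_minutes() < self.schedule.photophase_minutes

    def n_days(self) -> float:
        return len(self.counts) / MINUTES_PER_DAY


@dataclass
class SampleSheet:
    """Maps (monitor, channel) to fly, isofemale line, population, latitude."""

    table: pd.DataFrame

    REQUIRED = ("monitor", "channel", "fly_id", "line_id", "population_id", "latitude")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.table.duplicated(subset=["monitor", "channel"]).any():
            raise ValueError("sample sheet has duplicate (monitor, channel) rows")
        if not np.isfinite(self.table["latitude"].to_numpy(dtype=float)).all():
            raise ValueError("latitudes must be finite")

    @classmethod
    def read_csv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path))

    def lookup(self, monitor: str, channel: int):
        hit = self.table[
            (self.table["monitor"].astype(str) == str(monitor))
            & (self.table["channel"].astype(int) == int(channel))
        ]
        if hit.empty:
            return None
        return hit.iloc[0]


@dataclass(frozen=True)
class DamLayout:
    """Column positions (0-based) in a tab-delimited DAM monitor file.

    Defaults follow the common 42-column DAMSystem layout: index, date,
    time, status, six device/metadata columns, then counts for channels
    1-32.  ``status_ok`` is the status-code value meaning a valid reading;
    any other value marks the row as a gap.
    """

    date_col: int = 1
    time_col: int = 2
    status_col: int = 3
    first_count_col: int = 10
    n_channels: int = 32
    status_ok: str = "1"


_DATE_FORMATS = ("%d %b %y", "%d %b %Y", "%Y-%m-%d", "%d-%b-%y")


def _parse_row_timestamp(date_s: str, time_s: str, lineno: int) -> dt.datetime:
    for fmt in _DATE_FORMATS:
        try:
            d = dt.datetime.strptime(date_s.strip(), fmt).date()
            break
        except ValueError:
            continue
    else:
        raise DamParseError(f"line {lineno}: unparseable date {date_s!r}")
    try:
        t = dt.datetime.strptime(time_s.strip(), "%H:%M:%S").time()
    except ValueError:
        raise DamParseError(f"line {lineno}: unparseable time {time_s!r}") from None
    return dt.datetime.combine(d, t)


def read_dam_monitor_file(
    path,
    samplesheet: SampleSheet,
    schedule: LightSchedule,
    monitor: str | None = None,
    layout: DamLayout = DamLayout(),
    gap_policy: str = "zero_fill",
) -> list[BeamCrossSeries]:
    """Parse one DAM monitor file into per-fly beam-cross series.

    Rows whose status code differs from ``layout.status_ok`` are treated
    as gaps.  Under ``gap_policy="zero_fill"`` (default) gap minutes get
    count 0 and are flagged in ``gap_mask``; under ``"drop_day"`` every
    full ZT day containing a gap is removed (see :func:`drop_gap_days`).
    Channels absent from the sample sheet are skipped with a warning.
    """
    if gap_policy not in ("zero_fill", "drop_day"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    path = str(path)
    if monitor is None:
        import os

        monitor = os.path.splitext(os.path.basename(path))[0]

    timestamps: list[dt.datetime] = []
    rows: list[np.ndarray] = []
    gaps: list[bool] = []
    min_cols = layout.first_count_col + layout.n_channels
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < min_cols:
                raise DamParseError(
                    f"line {lineno}: expected >= {min_cols} tab-separated "
                    f"columns, found {len(fields)}"
                )
            ts = _parse_row_timestamp(
                fields[layout.date_col], fields[layout.time_col], lineno
            )
            if timestamps and ts <= timestamps[-1]:
                raise DamParseError(
                    f"line {lineno}: non-monotone timestamp {ts} after {timestamps[-1]}"
                )
            ok = fields[layout.status_col].strip() == layout.status_ok
            try:
                counts = np.array(
                    [
                        int(fields[layout.first_count_col + j])
                        for j in range(layout.n_channels)
                    ],
                    dtype=np.int64,
                )
            except ValueError as exc:
                raise DamParseError(f"line {lineno}: non-integer count ({exc})") from None
            timestamps.append(ts)
            rows.append(counts if ok else np.zeros(layout.n_channels, dtype=np.int64))
            gaps.append(not ok)

    if not timestamps:
        raise DamParseError(f"{path}: empty monitor file")

    # lay the readings on a contiguous minute grid; missing minutes are gaps
    start = timestamps[0]
    n_minutes = int((timestamps[-1] - start).total_seconds() // 60) + 1
    grid = np.zeros((n_minutes, layout.n_channels), dtype=np.int64)
    gap_mask = np.ones(n_minutes, dtype=bool)
    for ts, counts, gap in zip(timestamps, rows, gaps):
        i = int((ts - start).total_seconds() // 60)
        grid[i] = counts
        gap_mask[i] = gap

    out: list[BeamCrossSeries] = []
    for ch in range(1, layout.n_channels + 1):
        meta = samplesheet.lookup(monitor, ch)
        if meta is None:
            col = grid[:, ch - 1]
            if col.any():
                warnings.warn(
                    f"{monitor} channel {ch}: activity present but channel not in "
                    "sample sheet; skipped",
                    stacklevel=2,
                )
            continue
        series = BeamCrossSeries(
            fly_id=str(meta["fly_id"]),
            counts=grid[:, ch - 1].copy(),
            schedule=schedule,
            start_timestamp=start,
            line_id=str(meta["line_id"]),
            population_id=str(meta["population_id"]),
            latitude=float(meta["latitude"]),
            gap_mask=gap_mask.copy(),
        )
        if gap_policy == "drop_day":
            series = drop_gap_days(series)
        out.append(series)
    return out


def drop_gap_days(series: BeamCrossSeries) -> BeamCrossSeries:
    """Remove every full ZT day that contains a gap minute.

    The returned series starts at the first retained ZT00 and consists of
    whole, contiguous-in-index ZT days (intervening dropped days are
    spliced out; per-day statistics remain valid, absolute timing across
    the splice does not).
    """
    if series.gap_mask is None:
        return series
    first_zt00 = (-series.start_zt_minute) % MINUTES_PER_DAY
    n_full = (len(series) - first_zt00) // MINUTES_PER_DAY
    keep_chunks = []
    for d in range(n_full):
        sl = slice(first_zt00 + d * MINUTES_PER_DAY, first_zt00 + (d + 1) * MINUTES_PER_DAY)
        if not series.gap_mask[sl].any():
            keep_chunks.append(sl)
    counts = (
        np.concatenate([series.counts[sl] for sl in keep_chunks])
        if keep_chunks
        else np.empty(0, dtype=np.int64)
    )
    new_start = series.start_timestamp + dt.timedelta(minutes=first_zt00)
    return replace(
        series,
        counts=counts,
        gap_mask=np.zeros(len(counts), dtype=bool),
        start_timestamp=new_start,
    )


def write_dam_monitor_file(
    series_list: list[BeamCrossSeries],
    path,
    layout: DamLayout = DamLayout(),
) -> list[tuple[int, str]]:
    """Serialize series as one DAM monitor file (channels assigned in order).

    All series must share start timestamp and length.  Returns the
    (channel, fly_id) assignment.
    """
    if not series_list:
        raise ValueError("no series to write")
    if len(series_list) > layout.n_channels:
        raise ValueError(f"at most {layout.n_channels} series per monitor file")
    n = len(series_list[0])
    start = series_list[0].start_timestamp
    for s in series_list:
        if len(s) != n or s.start_timestamp != start:
            raise ValueError("all series must share start timestamp and length")
    assignment = [(ch + 1, s.fly_id) for ch, s in enumerate(series_list)]
    with open(path, "w") as fh:
        for i in range(n):
            ts = start + dt.timedelta(minutes=i)
            fields = [""] * (layout.first_count_col + layout.n_channels)
            fields[0] = str(i + 1)
            fields[layout.date_col] = ts.strftime("%d %b %y")
            fields[layout.time_col] = ts.strftime("%H:%M:%S")
            fields[layout.status_col] = layout.status_ok
            for j in range(layout.first_count_col):
                if not fields[j]:
                    fields[j] = "0"
            for ch, s in enumerate(series_list):
                fields[layout.first_count_col + ch] = str(int(s.counts[i]))
            for ch in range(len(series_list), layout.n_channels):
                fields[layout.first_count_col + ch] = "0"
            fh.write("\t".join(fields) + "\n")
    return assignment


def read_long_csv(path, schedule: LightSchedule) -> list[BeamCrossSeries]:
    """Read the long-format alternative: fly_id,timestamp,count rows.

    Optional columns line_id, population_id, latitude are carried through.
    Minutes must be contiguous per fly.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for fly_id, g in df.groupby("fly_id", sort=False):
        g = g.sort_values("timestamp")
        ts = g["timestamp"].dt.to_pydatetime()
        deltas = np.diff([t.timestamp() for t in ts])
        if len(deltas) and not np.allclose(deltas, 60.0):
            raise DamParseError(f"fly {fly_id}: timestamps are not contiguous minutes")
        out.append(
            BeamCrossSeries(
                fly_id=str(fly_id),
                counts=g["count"].to_numpy(),
                schedule=schedule,
                start_timestamp=ts[0],
                line_id=str(g["line_id"].iloc[0]) if "line_id" in g else "",
                population_id=str(g["population_id"].iloc[0])
                if "population_id" in g
                else "",
                latitude=float(g["latitude"].iloc[0]) if "latitude" in g else float("nan"),
            )
        )
    return out


def slice_experiment_days(
    series: BeamCrossSeries, first_day: int, last_day: int
) -> BeamCrossSeries:
    """Keep only full ZT days ``first_day..last_day`` (1-based, inclusive).

    Day 1 is the first full lights-on -> lights-on span of the recording.
    The standard analysis window for an 12-day recording is days 5-12,
    discarding the acclimation period.
    """
    if not (1 <= first_day <= last_day):
        raise ValueError("need 1 <= first_day <= last_day")
    first_zt00 = (-series.start_zt_minute) % MINUTES_PER_DAY
    start = first_zt00 + (first_day - 1) * MINUTES_PER_DAY
    stop = first_zt00 + last_day * MINUTES_PER_DAY
    if stop > len(series):
        avail = (len(series) - first_zt00) // MINUTES_PER_DAY
        raise ValueError(
            f"series has only {avail} full ZT days "
            f"(requested days {first_day}-{last_day})"
        )
    return replace(
        series,
        counts=series.counts[start:stop].copy(),
        gap_mask=None if series.gap_mask is None else series.gap_mask[start:stop].copy(),
        start_timestamp=series.start_timestamp + dt.timedelta(minutes=start),
    )


def write_phenotype_table(summaries: pd.DataFrame, path) -> None:
    """Write a tidy phenotype table (one row per unit/phase/metric) as CSV."""
    summaries.to_csv(path, index=False)
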