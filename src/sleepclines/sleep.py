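"""Sleep and activity phenotyping from per-minute beam-cross series.

Definitions (field-standard for Drosophila DAM data):

* **Sleep bout** — a maximal run of >= 5 consecutive minutes with zero beam
  crosses (threshold configurable).
* **Locomotor activity** — beam crosses per minute of phase (zeros included).
* **Walking speed** — beam crosses per *active* minute, i.e. excluding all
  zero-count minutes.  Undefined (NaN) when a phase has no active minute.
* **Exclusion rule** — a fly showing any 24 consecutive hours with 24 or
  fewer beam crosses is non-informative (dead or moribund) and is dropped.

Phenotypes are computed per fly, then averaged fly -> isofemale line ->
population (strict two-stage unweighted means; the population s.e.m. is
taken across line means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam import MINUTES_PER_DAY, BeamCrossSeries

__all__ = [
    "SleepBout",
    "FlyPhenotype",
    "filter_individuals",
    "detect_sleep_bouts",
    "compute_locomotor_activity",
    "compute_walking_speed",
    "compute_sleep_variables",
    "hourly_avg_bout_duration",
    "fly_phenotype",
    "phenotype_table",
    "aggregate",
]

PHASES = ("photophase", "scotophase")
DEFAULT_BOUT_THRESHOLD = 5
EXCLUSION_MAX_CROSSES = 24  # per any 24-h sliding window


@dataclass(frozen=True)
class SleepBout:
    """A maximal inactive run of at least the threshold length."""

    start_minute: int
    duration: int
    phase_at_start: str


def filter_individuals(
    series_list: list[BeamCrossSeries],
    max_crosses: int = EXCLUSION_MAX_CROSSES,
) -> tuple[list[BeamCrossSeries], pd.DataFrame]:
    """Drop non-informative flies (dead or nearly immobile).

    A fly is discarded if *any* 1440-minute sliding window of its recording
    totals ``max_crosses`` or fewer beam crosses.  Returns the kept series
    and a report of discarded flies with the first triggering window.
    """
    kept: list[BeamCrossSeries] = []
    rows = []
    for s in series_list:
        if len(s) < MINUTES_PER_DAY:
            raise ValueError(
                f"fly {s.fly_id}: series shorter than 24 h ({len(s)} min)"
            )
        c = np.concatenate([[0], np.cumsum(s.counts, dtype=np.int64)])
        window_sums = c[MINUTES_PER_DAY:] - c[:-MINUTES_PER_DAY]
        bad = np.nonzero(window_sums <= max_crosses)[0]
        if bad.size:
            rows.append(
                {
                    "fly_id": s.fly_id,
                    "line_id": s.line_id,
                    "population_id": s.population_id,
                    "window_start_minute": int(bad[0]),
                    "window_crosses": int(window_sums[bad[0]]),
                }
            )
        else:
            kept.append(s)
    report = pd.DataFrame(
        rows,
        columns=[
            "fly_id",
            "line_id",
            "population_id",
            "window_start_minute",
            "window_crosses",
        ],
    )
    return kept, report


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of every maximal zero run, boundaries included."""
    is_zero = np.asarray(counts) == 0
    if not is_zero.any():
        return []
    padded = np.concatenate([[False], is_zero, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def detect_sleep_bouts(
    series: BeamCrossSeries | np.ndarray,
    threshold: int = DEFAULT_BOUT_THRESHOLD,
) -> list[SleepBout]:
    """All maximal zero-count runs of length >= ``threshold`` minutes.

    Runs touching the series boundaries are counted from/to the boundary.
    The bout's phase label is that of its starting minute.
    """
    if isinstance(series, BeamCrossSeries):
        counts = series.counts
        photo = series.schedule.photophase_minutes
        zt0 = series.start_zt_minute
    else:
        counts = np.asarray(series)
        photo = MINUTES_PER_DAY // 2
        zt0 = 0
    bouts = []
    for start, length in _zero_runs(counts):
        if length >= threshold:
            zt = (zt0 + start) % MINUTES_PER_DAY
            phase = "photophase" if zt < photo else "scotophase"
            bouts.append(SleepBout(start, length, phase))
    return bouts


def compute_locomotor_activity(series: BeamCrossSeries, phase: str) -> float:
    """Beam crosses per minute of the given phase, averaged across days."""
    mask = _phase_mask(series, phase)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"series contains no {phase} minutes")
    return float(series.counts[mask].sum() / n)


def compute_walking_speed(series: BeamCrossSeries, phase: str) -> float:
    """Beam crosses per *active* minute of the phase; NaN if never active."""
    mask = _phase_mask(series, phase)
    counts = series.counts[mask]
    active = counts > 0
    if not active.any():
        return float("nan")
    return float(counts.sum() / active.sum())


def _phase_mask(series: BeamCrossSeries, phase: str) -> np.ndarray:
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    photo = series.phase_labels()
    return photo if phase == "photophase" else ~photo


def compute_sleep_variables(
    series: BeamCrossSeries,
    threshold: int = DEFAULT_BOUT_THRESHOLD,
    attribution: str = "split",
) -> dict[str, dict[str, float]]:
    """Per-phase sleep duration, bout number and average bout duration.

    Returns ``{phase: {"sleep_duration": min/day, "sleep_bout_number": /day,
    "avg_sleep_bout_duration": min}}``.

    A bout spanning the lights-on/off boundary is handled per
    ``attribution``: under ``"split"`` (default) its *minutes* are divided
    between phases for sleep_duration while the bout itself — count and full
    duration — goes to its starting phase for bout_number and
    avg_sleep_bout_duration; under ``"start"`` all minutes follow the
    starting phase too.
    """
    if attribution not in ("split", "start"):
        raise ValueError(f"unknown attribution {attribution!r}")
    n_days = len(series) / MINUTES_PER_DAY
    if n_days <= 0:
        raise ValueError("empty series")
    photo = series.phase_labels()
    bouts = detect_sleep_bouts(series, threshold)

    minutes = {p: 0.0 for p in PHASES}
    durations: dict[str, list[int]] = {p: [] for p in PHASES}
    for b in bouts:
        durations[b.phase_at_start].append(b.duration)
        if attribution == "start":
            minutes[b.phase_at_start] += b.duration
        else:
            span = photo[b.start_minute : b.start_minute + b.duration]
            in_photo = int(span.sum())
            minutes["photophase"] += in_photo
            minutes["scotophase"] += b.duration - in_photo

    out = {}
    for p in PHASES:
        n_bouts = len(durations[p])
        out[p] = {
            "sleep_duration": minutes[p] / n_days,
            "sleep_bout_number": n_bouts / n_days,
            "avg_sleep_bout_duration": (
                float(np.mean(durations[p])) if n_bouts else float("nan")
            ),
        }
    return out


def hourly_avg_bout_duration(
    series: BeamCrossSeries, threshold: int = DEFAULT_BOUT_THRESHOLD
) -> np.ndarray:
    """Mean sleep-bout duration per ZT hour of bout *start* (24-vector, NaN-padded)."""
    zt = series.zt_minutes()
    sums = np.zeros(24)
    counts = np.zeros(24)
    for b in detect_sleep_bouts(series, threshold):
        h = zt[b.start_minute] // 60
        sums[h] += b.duration
        counts[h] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@dataclass
class FlyPhenotype:
    """One fly's phenotype bundle across both phases."""

    fly_id: str
    line_id: str
    population_id: str
    latitude: float
    metrics: dict[str, dict[str, float]]  # phase -> metric -> value
    hourly_bout_duration: np.ndarray  # 24-vector by ZT hour of bout start


def fly_phenotype(
    series: BeamCrossSeries,
    threshold: int = DEFAULT_BOUT_THRESHOLD,
    attribution: str = "split",
) -> FlyPhenotype:
    sleep_vars = compute_sleep_variables(series, threshold, attribution)
    metrics = {}
    for phase in PHASES:
        metrics[phase] = {
            "locomotor_activity": compute_locomotor_activity(series, phase),
            "walking_speed": compute_walking_speed(series, phase),
            **sleep_vars[phase],
        }
    return FlyPhenotype(
        fly_id=series.fly_id,
        line_id=series.line_id,
        population_id=series.population_id,
        latitude=series.latitude,
        metrics=metrics,
        hourly_bout_duration=hourly_avg_bout_duration(series, threshold),
    )


def phenotype_table(
    series_list: list[BeamCrossSeries],
    threshold: int = DEFAULT_BOUT_THRESHOLD,
    attribution: str = "split",
) -> pd.DataFrame:
    """Tidy per-fly table: one row per fly with phase-suffixed metric columns
    plus the 24 hourly bout-duration columns ``hourly_bout_ZT00..ZT23``."""
    rows = []
    for s in series_list:
        p = fly_phenotype(s, threshold, attribution)
        row: dict = {
            "fly_id": p.fly_id,
            "line_id": p.line_id,
            "population_id": p.population_id,
            "latitude": p.latitude,
        }
        for phase in PHASES:
            for m, v in p.metrics[phase].items():
                row[f"{m}_{phase}"] = v
        for h in range(24):
            row[f"hourly_bout_ZT{h:02d}"] = p.hourly_bout_duration[h]
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate(fly_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage unweighted averaging: flies -> line means -> population means.

    Population rows carry, for every metric column, the mean of line means
    and the s.e.m. across lines (``<metric>_sem``) plus ``n_lines``.
    Missing values propagate as means over non-missing units.
    """
    meta = ["fly_id", "line_id", "population_id", "latitude"]
    value_cols = [c for c in fly_table.columns if c not in meta]
    line = (
        fly_table.groupby(["population_id", "line_id"], sort=True)
        .agg({**{c: "mean" for c in value_cols}, "latitude": "first"})
        .reset_index()
    )
    grp = line.groupby("population_id", sort=True)
    pop = grp.agg({**{c: "mean" for c in value_cols}, "latitude": "first"})
    sems = grp[value_cols].agg(lambda x: x.std(ddof=1) / np.sqrt(x.notna().sum()))
    sems.columns = [f"{c}_sem" for c in sems.columns]
    pop["n_lines"] = grp.size()
    pop = pd.concat([pop, sems], axis=1).reset_index()
    return line, pop
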