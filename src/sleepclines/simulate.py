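"""Synthetic DAM-like behavior and genomic fixtures.

The behavioral generator is a two-state (wake/sleep) alternating renewal
process on the 1-minute grid.  Run lengths are geometric (the discrete
memoryless distribution) with phase-specific means; a run's parameters are
fixed by the phase (photophase/scotophase) of its starting minute, so runs
may span the lights-on/lights-off boundary exactly as real bouts do.  Sleep
minutes record 0 beam crosses; wake minutes draw Poisson counts whose rate
can ramp up linearly late in the night to emulate sunrise anticipation.

Population sets impose a latitudinal cline on the *nighttime* sleep-bout
mean only (temperate flies: shorter night sleep bouts), with multiplicative
log-normal line effects — mirroring the empirical day/night contrast in
which only nighttime sleep-bout duration tracks latitude.

The genomic generator tiles a chromosome with 1-kb windows, draws window
mean F_ST values, flags a top fraction as outliers, and assigns per-timepoint
differential-expression (DE) flags whose odds are multiplied for genes
overlapping outlier windows — a programmable excess for exercising the
enrichment statistics.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dam import MINUTES_PER_DAY, BeamCrossSeries, LightSchedule

__all__ = [
    "BehaviorParams",
    "ClineConfig",
    "GenomeFixtureConfig",
    "PAPER_POPULATIONS",
    "TIMEPOINTS",
    "simulate_fly_series",
    "simulate_population_set",
    "simulate_gene_fixture",
    "inject_dead_fly",
]

TIMEPOINTS = ("ZT01", "ZT13", "ZT18", "ZT22")

#: The five sampled populations with their latitudes (degrees N):
#: Maine, Rhode Island, Virginia, Florida, Panama City.
PAPER_POPULATIONS: tuple[tuple[str, float], ...] = (
    ("ME", 44.6),
    ("RI", 41.8),
    ("VA", 37.5),
    ("FL", 30.3),
    ("PC", 9.0),
)


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the wake/sleep renewal process (minutes / crosses-per-minute).

    ``sleep_bout_mean_night`` is the clined parameter; the defaults below
    describe a temperate fly and are overridden per line by
    :func:`simulate_population_set`.  ``anticipation_gain`` multiplies the
    wake Poisson rate, ramping linearly from 1 at ``anticipation_start_zt``
    to the full gain at ZT24 (night only); gain 1 disables the ramp.
    """

    wake_rate_day: float = 2.0
    wake_rate_night: float = 1.0
    wake_bout_mean_day: float = 30.0
    wake_bout_mean_night: float = 10.0
    sleep_bout_mean_day: float = 10.0
    sleep_bout_mean_night: float = 30.0
    anticipation_start_zt: float = 21.0
    anticipation_gain: float = 2.0
    line_sd: float = 0.12
    death_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "wake_rate_day",
            "wake_rate_night",
            "wake_bout_mean_day",
            "wake_bout_mean_night",
            "sleep_bout_mean_day",
            "sleep_bout_mean_night",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.wake_rate_day < 0 or self.wake_rate_night < 0:
            raise ValueError("wake rates must be >= 0")
        for name in (
            "wake_bout_mean_day",
            "wake_bout_mean_night",
            "sleep_bout_mean_day",
            "sleep_bout_mean_night",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 minute")
        if not 18.0 <= self.anticipation_start_zt <= 24.0:
            raise ValueError("anticipation_start_zt must lie in [18, 24]")
        if not np.isfinite(self.anticipation_gain) or self.anticipation_gain <= 0:
            raise ValueError("anticipation_gain must be positive and finite")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError("death_prob must be a probability")


@dataclass(frozen=True)
class ClineConfig:
    """Design of a multi-population behavioral experiment.

    The expected nighttime sleep-bout mean of a population at latitude L is
    ``cline_intercept + cline_slope * L`` minutes; the defaults program a
    two-fold difference between 9 degrees N (60 min) and 44.6 degrees N
    (30 min), matching the observed roughly two-fold equatorial/temperate
    contrast.
    """

    populations: tuple[tuple[str, float], ...] = PAPER_POPULATIONS
    cline_intercept: float = 67.58
    cline_slope: float = -0.8427
    lines_per_pop: int = 8
    flies_per_line: int = 16
    n_days: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations) < 2:
            raise ValueError("need at least two populations")
        if min(self.lines_per_pop, self.flies_per_line, self.n_days) < 1:
            raise ValueError("lines_per_pop, flies_per_line and n_days must be >= 1")
        for pop, lat in self.populations:
            mean = self.cline_intercept + self.cline_slope * lat
            if mean <= 0:
                raise ValueError(
                    f"predicted sleep bout mean {mean:.2f} <= 0 at {pop} ({lat} deg N)"
                )

    def expected_night_bout_mean(self, latitude: float) -> float:
        return self.cline_intercept + self.cline_slope * latitude


@dataclass(frozen=True)
class GenomeFixtureConfig:
    """Design of a gene table + F_ST window fixture on one synthetic chromosome."""

    n_genes: int = 2000
    chrom_length: int = 5_000_000
    window_size: int = 1000
    outlier_fraction: float = 0.05
    de_base_prob: tuple[float, ...] = (0.12, 0.05, 0.05, 0.06)
    de_window_enrichment: float = 1.0
    direction_bias: tuple[float, ...] = (0.5, 0.65, 0.65, 0.65)
    fold_change_log_sd: float = 0.5
    expressed_prob: float = 0.85
    gene_length_mean: int = 2000
    chrom: str = "2L"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in (0, 1)")
        for p in (*self.de_base_prob, *self.direction_bias, self.expressed_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.de_base_prob) != len(TIMEPOINTS):
            raise ValueError(f"de_base_prob needs {len(TIMEPOINTS)} entries")
        if len(self.direction_bias) != len(TIMEPOINTS):
            raise ValueError(f"direction_bias needs {len(TIMEPOINTS)} entries")
        if self.de_window_enrichment <= 0:
            raise ValueError("de_window_enrichment must be positive")
        if self.chrom_length % self.window_size:
            raise ValueError("window grid must tile the chromosome exactly")


def _anticipation_multiplier(
    zt_minutes: np.ndarray, params: BehaviorParams
) -> np.ndarray:
    """Wake-rate multiplier per minute: linear ramp late at night, else 1."""
    zt_h = zt_minutes / 60.0
    mult = np.ones(len(zt_minutes))
    span = 24.0 - params.anticipation_start_zt
    if span > 0 and params.anticipation_gain != 1.0:
        in_ramp = zt_h >= params.anticipation_start_zt
        frac = (zt_h[in_ramp] - params.anticipation_start_zt) / span
        mult[in_ramp] = 1.0 + (params.anticipation_gain - 1.0) * frac
    return mult


class _GeomPool:
    """Buffered geometric draws with a fixed success probability."""

    def __init__(self, rng: np.random.Generator, mean: float, chunk: int = 512):
        self.rng = rng
        self.p = min(1.0, 1.0 / mean)
        self.chunk = chunk
        self.buf = rng.geometric(self.p, size=chunk)
        self.i = 0

    def next(self) -> int:
        if self.i >= len(self.buf):
            self.buf = self.rng.geometric(self.p, size=self.chunk)
            self.i = 0
        v = self.buf[self.i]
        self.i += 1
        return v


def simulate_fly_series(
    params: BehaviorParams,
    line_effect: float = 1.0,
    n_days: int = 8,
    seed: int | np.random.SeedSequence | None = 0,
    fly_id: str = "fly",
    line_id: str = "",
    population_id: str = "",
    latitude: float = float("nan"),
    schedule: LightSchedule | None = None,
    start_timestamp: dt.datetime | None = None,
    return_wake_mask: bool = False,
):
    """Simulate one fly for ``n_days`` full ZT days starting at ZT00.

    ``line_effect`` multiplies the nighttime sleep-bout mean (the line-level
    random effect).  Reproducible: the same seed yields the identical series.

    With ``return_wake_mask=True`` also returns the latent per-minute wake
    state — useful for checking realized run lengths against the generator
    parameters, since observed zero-count minutes include awake-but-still
    minutes (Poisson zeros) exactly as in real beam-cross data.
    """
    if line_effect <= 0 or not np.isfinite(line_effect):
        raise ValueError("line_effect must be positive and finite")
    schedule = schedule or LightSchedule()
    if start_timestamp is None:
        start_timestamp = dt.datetime.combine(
            dt.date(2011, 9, 1), schedule.lights_on_clock_time
        )
    rng = np.random.default_rng(seed)
    n_minutes = n_days * MINUTES_PER_DAY
    photo_min = schedule.photophase_minutes

    sleep_night = params.sleep_bout_mean_night * line_effect
    pools = {
        ("wake", True): _GeomPool(rng, params.wake_bout_mean_day),
        ("wake", False): _GeomPool(rng, params.wake_bout_mean_night),
        ("sleep", True): _GeomPool(rng, params.sleep_bout_mean_day),
        ("sleep", False): _GeomPool(rng, sleep_night),
    }

    wake_mask = np.zeros(n_minutes, dtype=bool)
    t = 0
    state = "wake"  # lights-on startle: begin the recording awake
    while t < n_minutes:
        is_day = (t % MINUTES_PER_DAY) < photo_min
        run = pools[(state, is_day)].next()
        end = min(t + run, n_minutes)
        if state == "wake":
            wake_mask[t:end] = True
        t = end
        state = "sleep" if state == "wake" else "wake"

    zt = np.arange(n_minutes) % MINUTES_PER_DAY
    rate = np.where(zt < photo_min, params.wake_rate_day, params.wake_rate_night)
    rate = rate * np.where(
        zt < photo_min, 1.0, _anticipation_multiplier(zt, params)
    )
    counts = np.zeros(n_minutes, dtype=np.int64)
    counts[wake_mask] = rng.poisson(rate[wake_mask])
    series = BeamCrossSeries(
        fly_id=fly_id,
        counts=counts,
        schedule=schedule,
        start_timestamp=start_timestamp,
        line_id=line_id,
        population_id=population_id,
        latitude=latitude,
    )
    if return_wake_mask:
        return series, wake_mask
    return series


def simulate_population_set(
    config: ClineConfig, params: BehaviorParams | None = None
) -> tuple[list[BeamCrossSeries], pd.DataFrame]:
    """Simulate a full multi-population experiment with line-level effects.

    Each population's nighttime sleep-bout mean follows the configured
    latitudinal cline; each isofemale line jitters it by a multiplicative
    log-normal effect of s.d. ``params.line_sd`` (on the log scale).  A
    fraction ``params.death_prob`` of flies die at a uniform random minute.

    Returns the series list and a truth table recording every realized
    parameter (one row per fly).
    """
    params = params or BehaviorParams()
    root = np.random.SeedSequence(config.seed)
    series_out: list[BeamCrossSeries] = []
    truth_rows = []
    n_lines_total = len(config.populations) * config.lines_per_pop
    line_seeds = root.spawn(n_lines_total + 1)
    meta_rng = np.random.default_rng(line_seeds[-1])

    li = 0
    for pop, lat in config.populations:
        base_mean = config.expected_night_bout_mean(lat)
        for l in range(config.lines_per_pop):
            line_id = f"{pop}_L{l + 1:02d}"
            line_rng = np.random.default_rng(line_seeds[li])
            line_mult = float(np.exp(line_rng.normal(0.0, params.line_sd)))
            fly_seeds = line_seeds[li].spawn(config.flies_per_line)
            li += 1
            for f in range(config.flies_per_line):
                fly_id = f"{line_id}_F{f + 1:02d}"
                series = simulate_fly_series(
                    replace(params, sleep_bout_mean_night=base_mean),
                    line_effect=line_mult,
                    n_days=config.n_days,
                    seed=fly_seeds[f],
                    fly_id=fly_id,
                    line_id=line_id,
                    population_id=pop,
                    latitude=lat,
                )
                died = bool(meta_rng.random() < params.death_prob)
                death_minute = -1
                if died:
                    death_minute = int(meta_rng.integers(0, len(series)))
                    series = inject_dead_fly(series, death_minute)
                series_out.append(series)
                truth_rows.append(
                    {
                        "fly_id": fly_id,
                        "line_id": line_id,
                        "population_id": pop,
                        "latitude": lat,
                        "pop_night_bout_mean": base_mean,
                        "line_multiplier": line_mult,
                        "line_night_bout_mean": base_mean * line_mult,
                        "died": died,
                        "death_minute": death_minute,
                    }
                )
    return series_out, pd.DataFrame(truth_rows)


def inject_dead_fly(series: BeamCrossSeries, death_minute: int) -> BeamCrossSeries:
    """Zero all counts from ``death_minute`` onward (a mid-experiment death)."""
    if death_minute < 0:
        raise ValueError("death_minute must be >= 0")
    counts = series.counts.copy()
    counts[death_minute:] = 0
    return replace(series, counts=counts)


def simulate_gene_fixture(
    config: GenomeFixtureConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a gene table and a 1-kb F_ST window table on one chromosome.

    Window mean F_ST values are Beta(1, 10) draws; the top
    ``outlier_fraction`` are flagged as outliers.  DE flags per timepoint
    are Bernoulli with base probability ``de_base_prob``; for genes that
    overlap a flagged window the odds are multiplied by
    ``de_window_enrichment``.  Coordinates are 1-based closed intervals.
    """
    rng = np.random.default_rng(config.seed)
    n_windows = config.chrom_length // config.window_size
    win_start = np.arange(n_windows, dtype=np.int64) * config.window_size + 1
    win_end = win_start + config.window_size - 1
    mean_fst = rng.beta(1.0, 10.0, size=n_windows)

    n_flag = int(np.ceil(config.outlier_fraction * n_windows))
    order = np.lexsort((win_start, -mean_fst))  # F_ST desc, position asc on ties
    outlier = np.zeros(n_windows, dtype=bool)
    outlier[order[:n_flag]] = True

    lengths = rng.geometric(1.0 / config.gene_length_mean, size=config.n_genes)
    lengths = np.clip(lengths, 200, None)
    if lengths.mean() * config.n_genes > config.chrom_length:
        import warnings

        warnings.warn(
            "total gene footprint exceeds chromosome length; genes will overlap",
            stacklevel=2,
        )
    starts = rng.integers(1, config.chrom_length - lengths + 1)
    ends = starts + lengths - 1

    # gene overlaps >= 1 flagged window?  windows tile the chromosome, so a
    # gene hits window w iff its span covers any flagged grid cell
    first_win = (starts - 1) // config.window_size
    last_win = (ends - 1) // config.window_size
    cum_flag = np.concatenate([[0], np.cumsum(outlier)])
    in_outlier = (cum_flag[last_win + 1] - cum_flag[first_win]) > 0

    expressed = rng.random(config.n_genes) < config.expressed_prob
    de_flags = {}
    directions = {}
    fold_changes = {}
    for ti, tp in enumerate(TIMEPOINTS):
        p = config.de_base_prob[ti]
        odds = p / (1.0 - p) if p < 1.0 else np.inf
        p_in = (
            1.0
            if np.isinf(odds)
            else (odds * config.de_window_enrichment)
            / (1.0 + odds * config.de_window_enrichment)
        )
        prob = np.where(in_outlier, p_in, p)
        de = expressed & (rng.random(config.n_genes) < prob)
        side_a = rng.random(config.n_genes) < config.direction_bias[ti]
        direction = np.where(de, np.where(side_a, "higher_in_A", "higher_in_B"), "none")
        fc = np.where(
            de, np.exp(np.abs(rng.normal(0.0, config.fold_change_log_sd, config.n_genes))), np.nan
        )
        de_flags[f"de_{tp}"] = de
        directions[f"dir_{tp}"] = direction
        fold_changes[f"fc_{tp}"] = fc

    genes = pd.DataFrame(
        {
            "gene_id": [f"FBgn{i:07d}" for i in range(config.n_genes)],
            "chrom": config.chrom,
            "start": starts,
            "end": ends,
            "expressed": expressed,
            **de_flags,
            **directions,
            **fold_changes,
        }
    )
    windows = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": win_start,
            "end": win_end,
            "mean_fst": mean_fst,
            "outlier": outlier,
        }
    )
    return genes, windows
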