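"""Sunrise-anticipation ramping and circadian phase/period estimation.

*Ramping*: late-night activity is binned in 30-minute ZT bins from ZT18.0
to ZT23.5 (12 bins), averaged over days then flies within an isofemale
line, and min-max normalized per line:

    normalized_t = (A_t - A_min) / (A_max - A_min)

with A_min/A_max the extremes of the line's 12 binned means.  Population
curves are unweighted means of line curves.  Regressing each bin's
population mean on latitude quantifies geographic variation in sunrise
anticipation.

*Free-running period* (constant-dark data): chi-square periodogram
(Sokolove-Bushell).  For a candidate period P (minutes) the data are folded
into K complete cycles of P columns; the statistic

    Q_P = K * sum_h (M_h - M)^2 / (sum_i (X_i - M)^2 / N)

is asymptotically chi-square with P - 1 degrees of freedom under an
arrhythmic null; the period estimate is the candidate maximizing Q_P
relative to its null quantile.

*Peak phase*: activity smoothed by a centered moving average, folded into
cycles of the (estimated or supplied) period, argmax located within the
morning or evening half-cycle per cycle and averaged across cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dam import MINUTES_PER_DAY, BeamCrossSeries
from .cline import regress_on_latitude

__all__ = [
    "RampingProfile",
    "RhythmEstimate",
    "compute_ramping_profile",
    "population_ramping",
    "ramping_cline_scan",
    "estimate_period",
    "estimate_phase",
    "rhythm_table",
]

RAMP_START_ZT = 18.0
RAMP_END_ZT = 24.0
RAMP_BIN_MINUTES = 30


@dataclass
class RampingProfile:
    """One line's late-night activity ramp (raw and min-max normalized)."""

    line_id: str
    bin_start_zt: np.ndarray  # hours, ZT18.0 .. ZT23.5
    activity: np.ndarray  # mean crosses per 30-min bin (days, then flies)
    a_min: float
    a_max: float
    normalized: np.ndarray | None  # None when a_max == a_min (flat line)

    @property
    def defined(self) -> bool:
        return self.normalized is not None


@dataclass
class RhythmEstimate:
    """Per-fly circadian estimates from constant-dark (DD) data."""

    fly_id: str
    line_id: str
    population_id: str
    free_running_period: float  # hours; NaN if no significant rhythm
    morning_peak_phase: float  # hours after subjective lights-on; NaN if flat
    evening_peak_phase: float


def compute_ramping_profile(
    series_list: list[BeamCrossSeries],
    line_id: str | None = None,
    start_zt: float = RAMP_START_ZT,
    end_zt: float = RAMP_END_ZT,
    bin_minutes: int = RAMP_BIN_MINUTES,
) -> RampingProfile:
    """Ramping profile of one isofemale line from its flies' series.

    Per fly and day, counts are summed in each 30-min bin; bin means are
    taken over days then averaged over flies; the 12-bin curve is min-max
    normalized.  A flat curve (A_max == A_min) yields ``normalized=None``.
    """
    if not series_list:
        raise ValueError("need at least one fly")
    line_id = line_id or series_list[0].line_id
    b0 = int(start_zt * 60)
    b1 = int(end_zt * 60)
    n_bins = (b1 - b0) // bin_minutes
    per_fly = []
    for s in series_list:
        zt = s.zt_minutes()
        in_win = (zt >= b0) & (zt < b1)
        which_bin = (zt[in_win] - b0) // bin_minutes
        n_days = max(1, round(len(s) / MINUTES_PER_DAY))
        sums = np.bincount(which_bin, weights=s.counts[in_win], minlength=n_bins)
        per_fly.append(sums / n_days)  # mean crosses per bin per day
    activity = np.mean(per_fly, axis=0)
    a_min, a_max = float(activity.min()), float(activity.max())
    if a_max > a_min:
        normalized = (activity - a_min) / (a_max - a_min)
    else:
        normalized = None
    return RampingProfile(
        line_id=line_id,
        bin_start_zt=b0 / 60.0 + np.arange(n_bins) * bin_minutes / 60.0,
        activity=activity,
        a_min=a_min,
        a_max=a_max,
        normalized=normalized,
    )


def population_ramping(profiles: list[RampingProfile]) -> np.ndarray:
    """Unweighted mean of defined line curves; undefined lines are excluded."""
    defined = [p.normalized for p in profiles if p.defined]
    skipped = [p.line_id for p in profiles if not p.defined]
    if skipped:
        warnings.warn(
            f"excluding flat ramping profiles for line(s): {skipped}", stacklevel=2
        )
    if not defined:
        raise ValueError("no line has a defined ramping profile")
    return np.mean(defined, axis=0)


def ramping_cline_scan(
    population_curves: dict[str, np.ndarray], latitudes: dict[str, float]
) -> pd.DataFrame:
    """Per-bin OLS of population mean normalized activity on latitude.

    Returns one row per 30-min bin with slope, r_squared and the two-sided
    slope p-value; with fewer than 3 populations (or a zero-variance bin)
    r_squared/p are NaN and a warning is issued.
    """
    pops = sorted(population_curves)
    lats = np.array([latitudes[p] for p in pops], dtype=float)
    curves = np.array([population_curves[p] for p in pops], dtype=float)
    n_bins = curves.shape[1]
    rows = []
    small = len(pops) < 3
    if small:
        warnings.warn(
            f"only {len(pops)} populations: per-bin regressions are degenerate",
            stacklevel=2,
        )
    for b in range(n_bins):
        y = curves[:, b]
        if small or np.allclose(y, y[0]):
            rows.append(
                {"bin": b, "slope": np.nan, "r_squared": 0.0 if not small else np.nan,
                 "p_value": np.nan}
            )
            continue
        res = regress_on_latitude(lats, y)
        rows.append(
            {"bin": b, "slope": res.slope, "r_squared": res.r_squared,
             "p_value": res.p_value}
        )
    out = pd.DataFrame(rows)
    out["bin_start_zt"] = RAMP_START_ZT + out["bin"] * RAMP_BIN_MINUTES / 60.0
    return out


def estimate_period(
    series: BeamCrossSeries | np.ndarray,
    min_period: float = 20.0,
    max_period: float = 28.0,
    step: float = 0.1,
    alpha: float = 0.05,
) -> float:
    """Free-running period (hours) by chi-square periodogram; NaN if arrhythmic.

    Candidate periods run from ``min_period`` to ``max_period`` in ``step``
    hour increments (rounded to whole minutes).  The winning candidate must
    exceed the Bonferroni-corrected chi-square null quantile at ``alpha``;
    otherwise no significant rhythm is reported (NaN).
    """
    x = series.counts if isinstance(series, BeamCrossSeries) else np.asarray(series)
    x = x.astype(float)
    n = len(x)
    if n < 2 * max_period * 60:
        raise ValueError(
            f"need >= 2 full cycles of the longest candidate period "
            f"({int(2 * max_period * 60)} min), got {n}"
        )
    denom = float(((x - x.mean()) ** 2).sum())
    if denom == 0.0:
        return float("nan")
    candidates = np.round(
        np.arange(min_period, max_period + step / 2, step) * 60
    ).astype(int)
    candidates = np.unique(candidates)
    best_margin = -np.inf
    best_period = float("nan")
    for p_min in candidates:
        k = n // p_min
        m = k * p_min
        folded = x[:m].reshape(k, p_min)
        col_means = folded.mean(axis=0)
        grand = x[:m].mean()
        denom_p = float(((x[:m] - grand) ** 2).sum())
        if denom_p == 0.0:
            continue
        q = m * k * float(((col_means - grand) ** 2).sum()) / denom_p
        crit = stats.chi2.ppf(1 - alpha / len(candidates), p_min - 1)
        margin = q - crit
        if margin > best_margin:
            best_margin = margin
            best_period = p_min / 60.0
    if best_margin <= 0:
        return float("nan")
    return best_period


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # centered moving average with edge shrinkage
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def estimate_phase(
    series: BeamCrossSeries | np.ndarray,
    component: str = "morning",
    period: float | None = None,
    smooth_minutes: int = 60,
    skip_first_days: int = 1,
) -> float:
    """Peak phase (hours after subjective lights-on) of one DD series.

    The series is smoothed (centered moving average, default 60 min),
    divided into cycles of the free-running ``period`` (estimated by
    :func:`estimate_period` when not supplied), and the peak located within
    the searched half-cycle — [0, period/2) for the morning component,
    [period/2, period) for the evening — in each complete cycle after the
    first ``skip_first_days`` transient cycles.  Cycle phases are averaged;
    a flat search window contributes nothing; all-flat yields NaN.  Ties
    within a window resolve to the earliest maximum.
    """
    if component not in ("morning", "evening"):
        raise ValueError("component must be 'morning' or 'evening'")
    x = series.counts if isinstance(series, BeamCrossSeries) else np.asarray(series)
    x = x.astype(float)
    if len(x) < 3 * MINUTES_PER_DAY:
        raise ValueError("need at least 3 days of DD data")
    if period is None:
        period = estimate_period(x)
        if np.isnan(period):
            return float("nan")
    cycle = int(round(period * 60))
    half = cycle // 2
    lo, hi = (0, half) if component == "morning" else (half, cycle)
    smoothed = _smooth(x, smooth_minutes)
    phases = []
    n_cycles = len(x) // cycle
    for c in range(skip_first_days, n_cycles):
        win = smoothed[c * cycle + lo : c * cycle + hi]
        if win.size == 0 or np.allclose(win, win[0]):
            continue
        phases.append((lo + int(np.argmax(win))) / 60.0)
    if not phases:
        return float("nan")
    return float(np.mean(phases))


def rhythm_table(
    series_list: list[BeamCrossSeries],
    period: float | None = None,
    **phase_kwargs,
) -> pd.DataFrame:
    """Per-fly period and morning/evening phase estimates, as a tidy table."""
    rows = []
    for s in series_list:
        per = estimate_period(s) if period is None else period
        morning = (
            estimate_phase(s, "morning", period=per, **phase_kwargs)
            if not np.isnan(per)
            else float("nan")
        )
        evening = (
            estimate_phase(s, "evening", period=per, **phase_kwargs)
            if not np.isnan(per)
            else float("nan")
        )
        rows.append(
            {
                "fly_id": s.fly_id,
                "line_id": s.line_id,
                "population_id": s.population_id,
                "free_running_period": per,
                "morning_peak_phase": morning,
                "evening_peak_phase": evening,
            }
        )
    return pd.DataFrame(rows)
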