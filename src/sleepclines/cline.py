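"""Latitudinal cline statistics and the nonparametric comparisons.

A latitudinal cline is tested by ordinary least squares of *population*
phenotypic means on latitude (the population, not the line or the fly, is
the unit of replication; with five populations the slope test has three
degrees of freedom).  Hour-by-hour scans regress each ZT hour's population
means on latitude and apply a Bonferroni correction over the 24 tests.
Group comparisons use Wilcoxon/Mann-Whitney rank-sum (two groups) or
Kruskal-Wallis (more), since DAM phenotypes are typically non-normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClineRegressionResult",
    "regress_on_latitude",
    "hourly_cline_scan",
    "nonparametric_compare",
    "kruskal_compare",
    "bonferroni_adjust",
]


@dataclass(frozen=True)
class ClineRegressionResult:
    """OLS of a population mean phenotype on latitude."""

    slope: float  # phenotype units per degree latitude
    intercept: float
    r_squared: float
    p_value: float  # two-sided slope test, t distribution, n-2 df
    n_populations: int
    metric: str = ""
    phase: str = ""


def regress_on_latitude(
    latitudes, values, metric: str = "", phase: str = ""
) -> ClineRegressionResult:
    """OLS regression of population means over latitude.

    Requires >= 3 populations with finite values and non-constant latitude.
    NaN values are dropped pairwise.
    """
    lat = np.asarray(latitudes, dtype=float)
    y = np.asarray(values, dtype=float)
    if lat.shape != y.shape:
        raise ValueError("latitudes and values must have equal length")
    ok = np.isfinite(lat) & np.isfinite(y)
    lat, y = lat[ok], y[ok]
    if len(lat) < 3:
        raise ValueError(f"need >= 3 populations, got {len(lat)}")
    if np.allclose(lat, lat[0]):
        raise ValueError("zero variance in latitude")
    res = stats.linregress(lat, y)
    return ClineRegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_populations=len(lat),
        metric=metric,
        phase=phase,
    )


def hourly_cline_scan(
    hourly_means: pd.DataFrame,
    latitudes: dict[str, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regress each ZT hour's population means on latitude, Bonferroni m=24.

    ``hourly_means``: rows = populations (index = population_id), 24 columns
    in ZT-hour order.  Hours where a population mean is missing drop that
    population from the regression for that hour.  Returns a 24-row table
    with slope, r_squared, p_value, and ``significant_after_correction``
    (reject iff p <= alpha / 24).
    """
    if hourly_means.shape[1] != 24:
        raise ValueError("hourly_means must have 24 columns (ZT00..ZT23)")
    lats = np.array([latitudes[p] for p in hourly_means.index], dtype=float)
    m = 24
    rows = []
    for h, col in enumerate(hourly_means.columns):
        y = hourly_means[col].to_numpy(dtype=float)
        finite = y[np.isfinite(y)]
        if len(finite) >= 3 and np.allclose(finite, finite[0]):
            rows.append(
                {"zt_hour": h, "slope": 0.0, "r_squared": 0.0, "p_value": np.nan}
            )
            continue
        try:
            res = regress_on_latitude(lats, y)
            rows.append(
                {
                    "zt_hour": h,
                    "slope": res.slope,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                }
            )
        except ValueError:
            rows.append(
                {"zt_hour": h, "slope": np.nan, "r_squared": np.nan, "p_value": np.nan}
            )
    out = pd.DataFrame(rows)
    out["bonferroni_alpha"] = alpha / m
    out["significant_after_correction"] = out["p_value"] <= alpha / m
    return out


def nonparametric_compare(group_a, group_b) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value (mid-ranks on ties).

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's automatic
    policy).  Identical groups give p = 1 (up to continuity handling,
    always >= 0.99).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def kruskal_compare(*groups) -> float:
    """Kruskal-Wallis p-value across two or more groups."""
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[np.isfinite(g)] for g in clean]
    if any(len(g) == 0 for g in clean):
        return float("nan")
    return float(stats.kruskal(*clean).pvalue)


def bonferroni_adjust(
    p_values, alpha: float = 0.05, m: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: reject iff p <= alpha / m.

    Returns (reject flags, adjusted p-values ``min(1, p*m)``).  ``m``
    defaults to the number of tests supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    reject = p <= alpha / m
    adjusted = np.minimum(1.0, p * m)
    return reject, adjusted
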