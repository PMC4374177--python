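"""Gene-window overlap and hypergeometric enrichment statistics.

Links differential expression (DE) between populations to genomic windows
of extreme allele-frequency differentiation (F_ST).  The chromosome is
tiled with 1-kb windows carrying mean F_ST; the top fraction (default 5%)
are *outlier* windows, candidate targets of spatially varying selection.
The central question — are DE genes over-represented among genes
overlapping outlier windows? — is answered by the exact hypergeometric
test on the contingency

    N = universe size (expressed genes)
    K = feature-positive genes (DE at >= 1 timepoint, or per-timepoint)
    n = genes overlapping >= 1 outlier window
    k = observed overlap of the two

with inclusive tails P(X >= k) (enrichment) and P(X <= k) (depletion),
summed in log space so tails of order 1e-25 do not underflow.

Coordinates are 1-based closed intervals (FlyBase/GFF convention); a gene
overlaps a window iff they share at least one base pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .cline import nonparametric_compare
from .simulate import TIMEPOINTS

__all__ = [
    "EnrichmentResult",
    "flag_outlier_windows",
    "overlap_genes_windows",
    "hypergeom_test",
    "enrichment_report",
    "timepoint_overlap_summary",
    "direction_summary",
    "select_candidate_genes",
    "read_gene_table",
    "read_window_table",
    "de_any",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """An (N, K, n, k) over/under-representation contingency with exact tails."""

    N: int
    K: int
    n: int
    k: int
    expected: float  # n * K / N
    fold_enrichment: float  # (k/n) / (K/N)
    percent_excess: float  # (fold_enrichment - 1) * 100
    p_upper: float  # P(X >= k): enrichment tail
    p_lower: float  # P(X <= k): depletion tail


def read_gene_table(path) -> pd.DataFrame:
    """Read the gene TSV (gene_id, chrom, start, end, expressed, de_*/dir_*/fc_*)."""
    df = pd.read_csv(path, sep="\t")
    for col in ["expressed"] + [f"de_{t}" for t in TIMEPOINTS if f"de_{t}" in df]:
        df[col] = df[col].astype(bool)
    return df


def read_window_table(path) -> pd.DataFrame:
    """Read the BED-like window TSV (chrom, start, end, mean_fst[, outlier])."""
    df = pd.read_csv(path, sep="\t")
    if "outlier" in df:
        df["outlier"] = df["outlier"].astype(bool)
    return df


def de_any(genes: pd.DataFrame, timepoints=TIMEPOINTS) -> pd.Series:
    """Boolean: gene differentially expressed at >= 1 of the given timepoints."""
    cols = [f"de_{t}" for t in timepoints]
    return genes[cols].any(axis=1)


def flag_outlier_windows(windows: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Flag the ``ceil(fraction * count)`` windows of highest mean F_ST.

    Ties at the threshold break by genomic position (chrom, then start
    ascending) so the flagged count is exact.  Returns a copy with an
    ``outlier`` column.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    fst = windows["mean_fst"].to_numpy(dtype=float)
    if not np.isfinite(fst).all():
        raise ValueError("mean_fst values must be finite")
    n_flag = int(np.ceil(fraction * len(windows)))
    chrom_rank = pd.factorize(windows["chrom"], sort=True)[0]
    order = np.lexsort((windows["start"].to_numpy(), chrom_rank, -fst))
    out = windows.copy()
    flags = np.zeros(len(windows), dtype=bool)
    flags[order[:n_flag]] = True
    out["outlier"] = flags
    return out


def overlap_genes_windows(
    genes: pd.DataFrame, windows: pd.DataFrame, flagged_only: bool = True
) -> set[str]:
    """Gene ids whose [start, end] shares >= 1 bp with any (flagged) window.

    Intervals are 1-based closed on both sides.  Genes on chromosomes
    absent from the window table are skipped with a warning.
    """
    win = windows[windows["outlier"]] if flagged_only and "outlier" in windows else windows
    trees: dict[str, IntervalTree] = {}
    for chrom, g in win.groupby("chrom"):
        # IntervalTree is half-open; +1 on the end closes the interval
        trees[chrom] = IntervalTree.from_tuples(
            zip(g["start"].astype(int), g["end"].astype(int) + 1)
        )
    hits: set[str] = set()
    unknown: set[str] = set()
    all_win_chroms = set(windows["chrom"].unique())
    for gene_id, chrom, start, end in zip(
        genes["gene_id"], genes["chrom"], genes["start"].astype(int), genes["end"].astype(int)
    ):
        if chrom not in all_win_chroms:
            unknown.add(chrom)
            continue
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(start, end + 1):
            hits.add(gene_id)
    if unknown:
        import warnings

        warnings.warn(
            f"genes on chromosome(s) {sorted(unknown)} have no windows; skipped",
            stacklevel=2,
        )
    return hits


def hypergeom_test(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Exact hypergeometric tails for an observed overlap k.

    Draw n from a universe of N containing K feature-positive items;
    ``p_upper = P(X >= k)`` and ``p_lower = P(X <= k)`` are inclusive and
    computed by log-space summation of point masses, stable down to
    ~1e-300.  ``k`` must lie in the support [max(0, n+K-N), min(n, K)].
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError("need K <= N and n <= N")
    lo, hi = max(0, n + K - N), min(n, K)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside support [{lo}, {hi}]")
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, N, K, n)
    p_upper = float(np.exp(logsumexp(logpmf[support >= k])))
    p_lower = float(np.exp(logsumexp(logpmf[support <= k])))
    expected = n * K / N if N else float("nan")
    if n > 0 and K > 0:
        fold = (k / n) / (K / N)
    else:
        fold = float("nan")
    return EnrichmentResult(
        N=N,
        K=K,
        n=n,
        k=k,
        expected=expected,
        fold_enrichment=fold,
        percent_excess=(fold - 1.0) * 100.0 if np.isfinite(fold) else float("nan"),
        p_upper=min(1.0, p_upper),
        p_lower=min(1.0, p_lower),
    )


def enrichment_report(
    genes: pd.DataFrame,
    windows: pd.DataFrame,
    timepoint: str | None = None,
    sample_gene_ids: set[str] | None = None,
) -> EnrichmentResult:
    """Hypergeometric enrichment of DE genes in a gene sample.

    Universe N = expressed genes; K = expressed genes DE at >= 1 timepoint
    (or at ``timepoint`` when given); sample n = expressed genes in
    ``sample_gene_ids`` — by default the genes overlapping flagged outlier
    F_ST windows; k = DE genes in the sample.
    """
    expressed = genes[genes["expressed"]].copy()
    if timepoint is None:
        feature = de_any(expressed)
    else:
        if f"de_{timepoint}" not in expressed:
            raise ValueError(f"no DE column for timepoint {timepoint!r}")
        feature = expressed[f"de_{timepoint}"]
    if sample_gene_ids is None:
        if "outlier" not in windows:
            windows = flag_outlier_windows(windows)
        sample_gene_ids = overlap_genes_windows(expressed, windows)
    in_sample = expressed["gene_id"].isin(sample_gene_ids)
    return hypergeom_test(
        N=len(expressed),
        K=int(feature.sum()),
        n=int(in_sample.sum()),
        k=int((feature & in_sample).sum()),
    )


def timepoint_overlap_summary(
    genes: pd.DataFrame, timepoints=TIMEPOINTS
) -> pd.Series:
    """Exact Venn partition of DE genes across timepoints.

    Returns counts indexed by the '+'-joined subset label (e.g.
    ``"ZT01+ZT13"``); cells are disjoint and sum to the number of genes DE
    at >= 1 timepoint.
    """
    flags = genes[[f"de_{t}" for t in timepoints]].to_numpy(dtype=bool)
    labels = []
    for row in flags:
        members = [t for t, f in zip(timepoints, row) if f]
        labels.append("+".join(members) if members else None)
    s = pd.Series(labels, dtype=object).dropna().value_counts()
    return s.sort_index()


def direction_summary(genes: pd.DataFrame, timepoint: str) -> dict:
    """Direction-of-change summary for one timepoint's DE genes.

    Counts genes over-expressed on each side, their arithmetic mean fold
    change, and the two-sided rank-sum p comparing the two fold-change
    sets; an empty side gives a missing p.
    """
    col = f"de_{timepoint}"
    if col not in genes:
        raise ValueError(f"no DE column for timepoint {timepoint!r}")
    de = genes[genes[col].astype(bool)]
    dirs = de[f"dir_{timepoint}"]
    fc = de[f"fc_{timepoint}"].to_numpy(dtype=float)
    a = fc[(dirs == "higher_in_A").to_numpy()]
    b = fc[(dirs == "higher_in_B").to_numpy()]
    return {
        "timepoint": timepoint,
        "n_higher_in_A": int(len(a)),
        "n_higher_in_B": int(len(b)),
        "mean_fold_A": float(np.nanmean(a)) if len(a) else float("nan"),
        "mean_fold_B": float(np.nanmean(b)) if len(b) else float("nan"),
        "p_value": (
            nonparametric_compare(a, b) if len(a) and len(b) else float("nan")
        ),
    }


def select_candidate_genes(go_mapping: pd.DataFrame, keywords) -> set[str]:
    """Genes annotated to >= 1 GO term whose name contains a keyword.

    ``go_mapping`` columns: gene_id, go_id, term_name.  Matching is
    case-insensitive substring (e.g. keyword "circadian rhythms" hits the
    term "circadian rhythms regulation").  An empty keyword list selects
    nothing.
    """
    kws = [k.lower() for k in keywords]
    if not kws:
        return set()
    names = go_mapping["term_name"].astype(str).str.lower()
    hit = names.apply(lambda t: any(k in t for k in kws))
    return set(go_mapping.loc[hit, "gene_id"])
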