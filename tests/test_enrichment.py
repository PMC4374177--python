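"""Outlier-window flagging, interval overlap, hypergeometric tails, Venn
partitions, direction summaries and GO-keyword candidate selection."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sleepclines.enrichment import (
    de_any,
    enrichment_report,
    flag_outlier_windows,
    hypergeom_test,
    overlap_genes_windows,
    select_candidate_genes,
    timepoint_overlap_summary,
    direction_summary,
)
from sleepclines.simulate import TIMEPOINTS


def _windows(fst_values, chrom="2L", size=1000):
    starts = np.arange(len(fst_values)) * size + 1
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + size - 1,
            "mean_fst": fst_values,
        }
    )


def _genes(coords, chrom="2L", **flags):
    n = len(coords)
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": chrom,
            "start": [c[0] for c in coords],
            "end": [c[1] for c in coords],
            "expressed": flags.pop("expressed", [True] * n),
        }
    )
    for t in TIMEPOINTS:
        df[f"de_{t}"] = flags.get(f"de_{t}", [False] * n)
    return df


class TestOutlierFlagging:
    def test_5_percent_of_1000_is_50(self, rng):
        w = flag_outlier_windows(_windows(rng.uniform(0, 1, 1000)), 0.05)
        assert w["outlier"].sum() == 50

    def test_all_equal_fst_positional_tiebreak_keeps_count(self):
        w = flag_outlier_windows(_windows(np.full(1000, 0.3)), 0.05)
        assert w["outlier"].sum() == 50
        assert w["outlier"].iloc[:50].all()  # earliest positions win ties

    def test_matches_sort_and_slice_oracle(self, rng):
        fst = rng.uniform(0, 1, 200)
        w = flag_outlier_windows(_windows(fst), 0.1)
        expected = set(np.argsort(-fst, kind="stable")[:20])
        assert set(np.nonzero(w["outlier"].to_numpy())[0]) == expected

    def test_invalid_fraction_rejected(self):
        for frac in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                flag_outlier_windows(_windows([0.1, 0.2]), frac)


class TestOverlap:
    def test_one_bp_overlap_counts(self):
        genes = _genes([(100, 199)])
        windows = _windows([0.9]).assign(start=150, end=1149, outlier=True)
        assert overlap_genes_windows(genes, windows) == {"g0"}

    def test_adjacent_closed_intervals_do_not_overlap(self):
        genes = _genes([(100, 199)])
        windows = _windows([0.9]).assign(start=200, end=1199, outlier=True)
        assert overlap_genes_windows(genes, windows) == set()

    def test_unknown_chromosome_skipped_with_warning(self):
        genes = _genes([(100, 199)], chrom="X")
        windows = _windows([0.9]).assign(outlier=True)
        with pytest.warns(UserWarning, match="no windows"):
            assert overlap_genes_windows(genes, windows) == set()

    def test_matches_quadratic_all_pairs_oracle(self, rng):
        for _ in range(50):
            g_start = rng.integers(1, 50_000, 40)
            g_len = rng.integers(1, 5000, 40)
            genes = _genes(list(zip(g_start, g_start + g_len - 1)))
            fst = rng.uniform(0, 1, 50)
            windows = flag_outlier_windows(_windows(fst), 0.2)
            got = overlap_genes_windows(genes, windows)
            flagged = windows[windows["outlier"]]
            expected = {
                row["gene_id"]
                for _, row in genes.iterrows()
                if any(
                    row["start"] <= w_end and row["end"] >= w_start
                    for w_start, w_end in zip(flagged["start"], flagged["end"])
                )
            }
            assert got == expected


class TestHypergeomTest:
    def test_enumeration_oracle_small_case(self):
        # N=10, K=4, n=5: P(X >= 3) counted over all C(10,5) draws
        res = hypergeom_test(10, 4, 5, 3)
        expected = (comb(4, 3) * comb(6, 2) + comb(4, 4) * comb(6, 1)) / comb(10, 5)
        assert res.p_upper == pytest.approx(expected)  # 66/252
        expected_lower = sum(
            comb(4, j) * comb(6, 5 - j) for j in (0, 1, 2, 3)
        ) / comb(10, 5)
        assert res.p_lower == pytest.approx(expected_lower)

    def test_sample_equals_universe(self):
        res = hypergeom_test(10, 4, 10, 4)
        assert res.p_upper == pytest.approx(1.0)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_tails_sum_identity(self, rng):
        for _ in range(20):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo, hi = max(0, n + K - N), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            res = hypergeom_test(N, K, n, k)
            pmf_k = hypergeom.pmf(k, N, K, n)
            assert res.p_upper + res.p_lower == pytest.approx(1.0 + pmf_k)
            assert 0.0 <= res.p_upper <= 1.0 and 0.0 <= res.p_lower <= 1.0

    def test_upper_tail_nonincreasing_in_k(self):
        ps = [hypergeom_test(100, 30, 40, k).p_upper for k in range(5, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_agrees_with_sf_cdf_in_extreme_tail(self):
        res = hypergeom_test(13072, 2119, 133, 74)
        assert res.p_upper == pytest.approx(
            float(hypergeom.sf(73, 13072, 2119, 133)), rel=1e-9
        )
        assert res.p_upper < 1e-20  # no underflow in log-space summation

    def test_out_of_support_k_rejected(self):
        with pytest.raises(ValueError, match="support"):
            hypergeom_test(10, 4, 5, 6)

    @pytest.mark.parametrize("bad", [(10, 12, 5, 3), (10, 4, 12, 3)])
    def test_invalid_contingency_rejected(self, bad):
        with pytest.raises(ValueError):
            hypergeom_test(*bad)


class TestPublishedContingencies:
    """Exact recomputation from printed genome-wide DE / outlier-window counts."""

    def test_fst_window_enrichment(self):
        # 13072 expressed genes, 2119 DE; 1854 in outlier windows, 391 DE
        res = hypergeom_test(13072, 2119, 1854, 391)
        assert res.p_upper < 1.4e-9
        assert res.percent_excess == pytest.approx(30, abs=1)

    def test_circadian_candidate_enrichment_is_two_fold(self):
        res = hypergeom_test(13072, 2119, 237, 76)
        assert res.fold_enrichment == pytest.approx(2.0, abs=0.05)
        assert res.p_upper == pytest.approx(8.8e-10, rel=1.0)

    def test_behavioral_state_gene_enrichment(self):
        res = hypergeom_test(13072, 2119, 133, 74)
        assert res.p_upper == pytest.approx(1.47e-25, rel=1.0)


class TestEnrichmentReport:
    def test_counts_built_from_gene_flags(self):
        genes = _genes(
            [(1, 500), (2000, 2500), (10_000, 10_500), (20_000, 20_500)],
            de_ZT01=[True, True, False, False],
        )
        windows = _windows([0.9, 0.1, 0.1, 0.1, 0.1]).assign(
            outlier=[True, False, False, False, False]
        )
        res = enrichment_report(genes, windows, timepoint="ZT01")
        assert (res.N, res.K, res.n, res.k) == (4, 2, 1, 1)

    def test_proportional_sample_gives_fold_one(self):
        res = hypergeom_test(1000, 100, 500, 50)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.percent_excess == pytest.approx(0.0)


class TestVennPartition:
    def test_gene_de_everywhere_counts_only_in_four_way_cell(self):
        genes = _genes([(1, 10)], **{f"de_{t}": [True] for t in TIMEPOINTS})
        venn = timepoint_overlap_summary(genes)
        assert venn.to_dict() == {"+".join(TIMEPOINTS): 1}

    def test_hand_set_partition(self):
        genes = _genes(
            [(1, 10), (20, 30), (40, 50)],
            de_ZT01=[True, True, False],
            de_ZT13=[False, True, False],
            de_ZT18=[False, False, False],
            de_ZT22=[False, False, True],
        )
        venn = timepoint_overlap_summary(genes)
        assert venn.to_dict() == {"ZT01": 1, "ZT01+ZT13": 1, "ZT22": 1}

    def test_partition_disjoint_and_exhaustive(self, rng):
        n = 300
        flags = {f"de_{t}": rng.random(n) < 0.3 for t in TIMEPOINTS}
        genes = _genes([(i * 10 + 1, i * 10 + 5) for i in range(n)], **flags)
        venn = timepoint_overlap_summary(genes)
        assert venn.sum() == int(de_any(genes).sum())
        # brute-force subset classification
        mat = np.column_stack([flags[f"de_{t}"] for t in TIMEPOINTS])
        for label, count in venn.items():
            members = label.split("+")
            mask = np.ones(n, dtype=bool)
            for i, t in enumerate(TIMEPOINTS):
                mask &= mat[:, i] == (t in members)
            assert count == mask.sum()


class TestDirectionSummary:
    def test_hand_set_four_gene_table(self):
        genes = _genes(
            [(1, 10), (20, 30), (40, 50), (60, 70)],
            de_ZT01=[True, True, True, False],
        )
        genes["dir_ZT01"] = ["higher_in_A", "higher_in_A", "higher_in_B", "none"]
        genes["fc_ZT01"] = [2.0, 4.0, 1.5, np.nan]
        s = direction_summary(genes, "ZT01")
        assert s["n_higher_in_A"] == 2
        assert s["n_higher_in_B"] == 1
        assert s["mean_fold_A"] == pytest.approx(3.0)
        assert s["mean_fold_B"] == pytest.approx(1.5)

    def test_one_sided_table_gives_missing_p(self):
        genes = _genes([(1, 10)], de_ZT13=[True])
        genes["dir_ZT13"] = ["higher_in_A"]
        genes["fc_ZT13"] = [2.0]
        s = direction_summary(genes, "ZT13")
        assert s["n_higher_in_B"] == 0
        assert np.isnan(s["p_value"])

    def test_symmetric_folds_give_null_uniform_p(self, rng):
        pvals = []
        for _ in range(200):
            n = 60
            genes = _genes(
                [(i * 100 + 1, i * 100 + 50) for i in range(n)], de_ZT18=[True] * n
            )
            genes["dir_ZT18"] = rng.choice(["higher_in_A", "higher_in_B"], n)
            genes["fc_ZT18"] = np.exp(np.abs(rng.normal(0, 0.5, n)))
            pvals.append(direction_summary(genes, "ZT18")["p_value"])
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.05 + 2 * np.sqrt(
            0.05 * 0.95 / 200
        )


class TestCandidateSelection:
    MAPPING = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5"],
            "go_id": ["GO:1", "GO:2", "GO:3", "GO:4", "GO:5"],
            "term_name": [
                "circadian rhythms regulation",
                "Dopamine biosynthesis",
                "wing development",
                "sleep homeostasis",
                "locomotion behavior control",
            ],
        }
    )
    KEYWORDS = [
        "sleep",
        "catecholamine",
        "dopamine",
        "serotonine",
        "circadian rhythms",
        "locomotion behavior",
    ]

    def test_substring_and_case_insensitive_match(self):
        assert select_candidate_genes(self.MAPPING, self.KEYWORDS) == {
            "g1",
            "g2",
            "g4",
            "g5",
        }

    def test_empty_keyword_list_selects_nothing(self):
        assert select_candidate_genes(self.MAPPING, []) == set()

    def test_gene_annotated_to_multiple_matching_terms_counted_once(self):
        mapping = pd.concat([self.MAPPING, self.MAPPING.iloc[[0]]], ignore_index=True)
        got = select_candidate_genes(mapping, ["circadian rhythms"])
        assert got == {"g1"}
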