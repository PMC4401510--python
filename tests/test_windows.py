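"""Window summaries, SNP-count clusters, empirical p-values, outliers."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    ConfigurationError,
    DomainError,
    GeneRecord,
    assign_clusters,
    associate_genes,
    empirical_pvalues,
    intersect_outliers,
    select_outliers,
    summarize_windows,
)


def scores_df(positions, stds, chromosome="1"):
    return pd.DataFrame(
        {"chromosome": chromosome, "position": positions, "std": stds}
    )


def null_windows(n, seed=0, cluster=1, n_snps=100):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "chromosome": "1",
            "start": np.arange(n) * 50_000,
            "end": (np.arange(n) + 1) * 50_000,
            "n_snps": n_snps,
            "summary": rng.normal(size=n),
            "cluster": cluster,
        }
    )


class TestSummarize:
    def test_max_and_count_in_single_window(self):
        win = summarize_windows(scores_df([1000, 2000, 3000], [0.5, 2.5, -1.0]))
        assert len(win) == 1
        assert win.loc[0, "summary"] == 2.5
        assert win.loc[0, "n_snps"] == 3

    def test_empty_windows_absent(self):
        win = summarize_windows(scores_df([1000, 260_000], [1.0, 2.0]))
        assert list(win["start"]) == [0, 250_000]

    def test_boundary_position_goes_to_upper_window(self):
        win = summarize_windows(scores_df([97_650_000], [1.0]))
        assert win.loc[0, "start"] == 97_650_000
        assert win.loc[0, "end"] == 97_700_000


class TestClusters:
    @pytest.mark.parametrize(
        "n_snps,cluster", [(1, 1), (349, 1), (350, 2), (699, 2), (700, 3), (1049, 3), (1050, 4), (5000, 4)]
    )
    def test_cluster_bounds(self, n_snps, cluster):
        win = null_windows(1)
        win["n_snps"] = n_snps
        assert assign_clusters(win).loc[0, "cluster"] == cluster


class TestEmpiricalP:
    def test_distinct_summaries_direct_count(self):
        win = null_windows(5)
        win["summary"] = [5.0, 4.0, 3.0, 2.0, 1.0]
        p = empirical_pvalues(win)["empirical_p"]
        assert list(p) == [0.0, 0.2, 0.4, 0.6, 0.8]

    def test_cluster_maximum_gets_zero(self):
        win = null_windows(7, seed=3)
        p = empirical_pvalues(win)
        assert p.loc[p["summary"].idxmax(), "empirical_p"] == 0.0

    def test_tied_maxima_both_zero(self):
        win = null_windows(3)
        win["summary"] = [3.0, 3.0, 1.0]
        p = empirical_pvalues(win)["empirical_p"]
        assert list(p) == [0.0, 0.0, 2 / 3]

    def test_shuffled_input_same_pvalues(self):
        win = null_windows(50, seed=9)
        p1 = empirical_pvalues(win)
        shuffled = win.sample(frac=1.0, random_state=1)
        p2 = empirical_pvalues(shuffled).sort_index()
        assert np.array_equal(p1["empirical_p"], p2["empirical_p"])

    def test_rank_consistency_within_cluster(self):
        win = null_windows(40, seed=5)
        p = empirical_pvalues(win).sort_values("summary", ascending=False)
        assert (np.diff(p["empirical_p"]) >= 0).all()

    def test_clusters_independent(self):
        win = pd.concat([null_windows(10, seed=1, cluster=1), null_windows(10, seed=2, cluster=2)])
        win = win.reset_index(drop=True)
        p = empirical_pvalues(win)
        for c in (1, 2):
            grp = p[p["cluster"] == c]
            assert grp["empirical_p"].min() == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            empirical_pvalues(null_windows(0))


class TestSelect:
    def test_500_distinct_null_windows_give_exactly_5(self):
        win = null_windows(500, seed=21)
        win["summary"] = np.abs(win["summary"]) + 0.001  # positive, distinct
        assert win["summary"].nunique() == 500
        out = select_outliers(empirical_pvalues(win), 0.01)
        assert len(out) == 5
        # brute force: the 5 largest summaries
        top5 = set(win.nlargest(5, "summary").index)
        assert set(win.index[win["summary"].isin(out["summary"])]) == top5

    def test_no_pvalue_below_cutoff_gives_empty(self):
        win = empirical_pvalues(null_windows(10, seed=2))
        assert len(select_outliers(win, cutoff=0.0)) == 0

    def test_negative_summaries_filtered_by_default(self):
        win = null_windows(5)
        win["summary"] = [-5.0, -4.0, -3.0, -2.0, -1.0]
        win = empirical_pvalues(win)
        assert len(select_outliers(win, cutoff=0.3)) == 0
        assert len(select_outliers(win, cutoff=0.3, positive_only=False)) > 0

    def test_null_calibration_bound(self):
        # fraction with p < 0.01 is at most 0.01 + 1/N per cluster
        win = empirical_pvalues(null_windows(300, seed=7))
        frac = (win["empirical_p"] < 0.01).mean()
        assert frac <= 0.01 + 1 / 300 + 1e-12


class TestGenes:
    windows = pd.DataFrame(
        {
            "chromosome": ["1"],
            "start": [15_000],
            "end": [65_000],
            "n_snps": [10],
            "summary": [3.0],
            "cluster": [1],
            "empirical_p": [0.0],
        }
    )

    def test_overlapping_gene_associated(self):
        out = associate_genes(self.windows, [GeneRecord("g", "1", 10_000, 20_000)])
        assert out.loc[0, "associated_genes"] == "g"

    def test_abutting_gene_not_associated(self):
        out = associate_genes(self.windows, [GeneRecord("g", "1", 65_000, 70_000)])
        assert out.loc[0, "associated_genes"] == ""

    def test_two_genes_in_one_window(self):
        genes = [
            GeneRecord("g1", "1", 20_000, 30_000),
            GeneRecord("g2", "1", 40_000, 50_000),
        ]
        out = associate_genes(self.windows, genes)
        assert out.loc[0, "associated_genes"] == "g1,g2"

    def test_other_chromosome_ignored(self):
        out = associate_genes(self.windows, [GeneRecord("g", "2", 20_000, 30_000)])
        assert out.loc[0, "associated_genes"] == ""


def outlier_table(starts, label="x"):
    return pd.DataFrame(
        {
            "chromosome": "1",
            "start": starts,
            "end": np.asarray(starts) + 50_000,
            "n_snps": 10,
            "summary": 3.0,
            "cluster": 1,
            "empirical_p": 0.001,
            "associated_genes": label,
        }
    )


class TestIntersect:
    def test_region_in_all_comparisons_kept(self):
        per = {
            "c1": outlier_table([0, 50_000]),
            "c2": outlier_table([50_000, 100_000]),
            "c3": outlier_table([50_000]),
        }
        table, venn = intersect_outliers(per)
        assert list(table["start"]) == [50_000]
        assert venn["intersection"] == 1
        assert venn["per_comparison"] == {"c1": 2, "c2": 2, "c3": 1}
        assert venn["pairwise"]["c1&c2"] == 1

    def test_two_of_three_excluded_but_counted(self):
        per = {
            "c1": outlier_table([0]),
            "c2": outlier_table([0]),
            "c3": outlier_table([50_000]),
        }
        table, venn = intersect_outliers(per)
        assert len(table) == 0
        assert venn["pairwise"]["c1&c2"] == 1

    def test_empty_map_rejected(self):
        with pytest.raises(DomainError):
            intersect_outliers({})

    def test_mismatched_grids_rejected(self):
        bad = outlier_table([0])
        bad["end"] = bad["start"] + 10_000
        with pytest.raises(ConfigurationError):
            intersect_outliers({"a": outlier_table([0]), "b": bad})

    def test_gene_union_and_columns(self):
        per = {
            "c1": outlier_table([0], label="g1"),
            "c2": outlier_table([0], label="g1,g2"),
        }
        table, _ = intersect_outliers(per)
        assert table.loc[0, "associated_genes"] == "g1,g2"
        assert {"xpehh_c1", "p_c1", "xpehh_c2", "p_c2"} <= set(table.columns)
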