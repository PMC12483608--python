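"""Module scoring, cluster enrichment, DE and signature intersection."""

import numpy as np
import pandas as pd
import pytest

import divscreen as ds
from divscreen.modules import resolve_module_genes
from divscreen.stats import bh_adjust
from conftest import make_adata
from test_stats import ranksum_oracle


def _normed_random(seed, n_cells=60, n_genes=120):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(5, (n_cells, n_genes)) + 1
    return ds.normalize_cp10k_log(make_adata(counts))


class TestModuleScore:
    def test_null_module_scores_center_near_zero(self):
        adata = _normed_random(0)
        module = [f"g{j}" for j in range(0, 120, 10)]  # arbitrary genes, no signal
        scores = ds.module_score(adata, module, seed=0)
        assert abs(scores.mean()) < 0.05

    def test_constant_offset_cell_unchanged_score(self):
        # adding a constant to every gene of one cell cancels in the difference
        adata = _normed_random(1)
        scorer = ds.ModuleScorer(["g0", "g5"], random_state=0)
        scorer.fit(adata.X, feature_names=list(adata.var_names))
        base = scorer.transform(adata.X)
        shifted = np.array(adata.X)
        shifted[3] += 2.5
        out = scorer.transform(shifted)
        assert out[3] - base[3] == pytest.approx(2.5 - 2.5, abs=1e-12)
        assert np.allclose(np.delete(out, 3), np.delete(base, 3))

    def test_delta_construction(self):
        # module genes exceed their bin mean by exactly delta in one cell
        X = np.tile(np.linspace(1, 2, 10), (4, 1))
        delta = 0.7
        X[2, [1, 3]] += delta
        scorer = ds.ModuleScorer(["g1", "g3"], n_bins=1, n_ctrl=100, random_state=0)
        scorer.fit(X, feature_names=[f"g{j}" for j in range(10)])
        scores = scorer.transform(X)
        # controls come from the same single bin; cells 0,1,3 score ~0
        assert scores[2] - scores[0] == pytest.approx(delta, abs=1e-9)

    def test_missing_genes_reported_and_alias_applied(self):
        adata = _normed_random(2)
        adata.var_names = ["FUT4"] + [f"g{j}" for j in range(1, adata.n_vars)]
        scores = ds.module_score(adata, ["SSEA1", "g1", "NOPE"], seed=0)
        assert scores.attrs["aliases_applied"] == {"SSEA1": "FUT4"}
        assert scores.attrs["missing_genes"] == ["NOPE"]
        with pytest.raises(ValueError, match="no module gene"):
            ds.module_score(adata, ["XXX"], seed=0)

    def test_rare_cluster_scores_highest(self, default_cohort):
        cohort, norm = default_cohort
        scores = ds.module_score(norm, cohort.truth["module_genes"], seed=0)
        means = scores.groupby(norm.obs["cluster"]).mean()
        assert means.idxmax() == "rare"


class TestClusterEnrichment:
    def test_hand_worked_three_clusters(self):
        feature = np.array([3, 4, 5, 6, 1, 2, 2, 1, 0, 1, 1, 0], dtype=float)
        clusters = np.array(["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        summary, pairs = ds.cluster_enrichment(feature, clusters)
        p_ab = pairs.set_index(["cluster_a", "cluster_b"]).loc[("A", "B"), "p"]
        assert p_ab == pytest.approx(ranksum_oracle([3, 4, 5, 6], [1, 2, 2, 1]))
        assert p_ab == pytest.approx(2 / 70)
        # A's max_fdr = larger BH-adjusted value of its two pairs, step-up by hand
        expected_fdr = bh_adjust(pairs["p"].to_numpy())
        mask = (pairs["cluster_a"] == "A") | (pairs["cluster_b"] == "A")
        assert summary.loc["A", "max_fdr"] == pytest.approx(expected_fdr[mask.to_numpy()].max())
        assert summary.loc["A", "enriched"]

    def test_constant_feature_all_p_one(self):
        feature = np.ones(12)
        clusters = np.array(["A", "B", "C"] * 4)
        summary, pairs = ds.cluster_enrichment(feature, clusters)
        assert (pairs["p"] == 1.0).all()
        assert (summary["max_fdr"] == 1.0).all()
        assert not summary["enriched"].any()

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        feature = rng.normal(size=30)
        clusters = np.array(["A", "B", "C"] * 10)
        s1, _ = ds.cluster_enrichment(feature, clusters)
        relabeled = np.array([{"A": "Z", "B": "Y", "C": "X"}[c] for c in clusters])
        s2, _ = ds.cluster_enrichment(feature, relabeled)
        for old, new in [("A", "Z"), ("B", "Y"), ("C", "X")]:
            assert s1.loc[old, "max_fdr"] == pytest.approx(s2.loc[new, "max_fdr"])

    def test_singleton_cluster_excluded_with_warning(self):
        feature = np.array([1.0, 2, 3, 4, 5])
        clusters = np.array(["A", "A", "B", "B", "S"])
        with pytest.warns(UserWarning, match="singleton"):
            summary, _ = ds.cluster_enrichment(feature, clusters)
        assert "S" not in summary.index

    def test_null_clusters_rarely_significant(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            feature = rng.normal(size=24)
            clusters = np.repeat(["A", "B", "C"], 8)
            summary, _ = ds.cluster_enrichment(feature, clusters)
            hits += summary["max_fdr"].min() < 0.05
        assert hits / n_sim <= 0.07


class TestDifferentialExpression:
    def _clustered(self, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(5, (30, 40)) + 1
        counts[:6, 0] += 40  # gene g0 high only in the target cluster
        obs = pd.DataFrame(
            {"cluster": ["T"] * 6 + ["R"] * 24}, index=[f"c{i}" for i in range(30)]
        )
        return ds.normalize_cp10k_log(make_adata(counts, obs=obs))

    def test_marker_gene_detected_up(self):
        res = ds.de_one_vs_rest(self._clustered(), "cluster", "T", fdr_max=0.05)
        assert "g0" in res.index
        assert res.loc["g0", "direction"] == "up"

    def test_threshold_monotonicity_and_noop(self):
        adata = self._clustered()
        strict = ds.de_one_vs_rest(adata, "cluster", "T", fdr_max=0.005)
        loose = ds.de_one_vs_rest(adata, "cluster", "T", fdr_max=0.05)
        assert set(strict.index) <= set(loose.index)
        everything = ds.de_one_vs_rest(adata, "cluster", "T", fdr_max=1.01, lfc_min=-np.inf)
        assert len(everything) == adata.n_vars

    def test_absent_cluster_errors(self):
        with pytest.raises(ValueError, match="not found"):
            ds.de_one_vs_rest(self._clustered(), "cluster", "ZZZ")

    def test_null_one_vs_rest_controls_false_calls(self):
        rng = np.random.default_rng(5)
        total_rows = 0
        for _ in range(50):
            counts = rng.poisson(5, (20, 50)) + 1
            obs = pd.DataFrame({"cluster": ["T"] * 8 + ["R"] * 12},
                               index=[f"c{i}" for i in range(20)])
            adata = ds.normalize_cp10k_log(make_adata(counts, obs=obs))
            total_rows += len(ds.de_one_vs_rest(adata, "cluster", "T", fdr_max=0.05))
        # full null: expected passing rows per sim well under 2x fdr_max per gene
        assert total_rows / (50 * 50) <= 2 * 0.05

    def test_two_group_identical_zero_rows(self):
        vals = np.tile(np.arange(4, dtype=float), (5, 2))  # trt replicates == ctrl
        table = pd.DataFrame(vals, index=[f"bg{i}" for i in range(5)],
                             columns=[f"ctrl_{i}" for i in range(4)] + [f"trt_{i}" for i in range(4)])
        assert len(ds.de_two_group(table)) == 0

    def test_two_group_complete_separation_p(self):
        table = pd.DataFrame(
            [[1, 2, 3, 4, 10, 11, 12, 13]], index=["bg0"],
            columns=[f"ctrl_{i}" for i in range(4)] + [f"trt_{i}" for i in range(4)],
        )
        res = ds.de_two_group(table)
        assert res.loc["bg0", "p"] == pytest.approx(2 / 70)
        assert res.loc["bg0", "direction"] == "up"

    def test_two_group_needs_three_replicates(self):
        table = pd.DataFrame([[1, 2, 3, 4]], index=["bg0"],
                             columns=["ctrl_1", "ctrl_2", "trt_1", "trt_2"])
        with pytest.raises(ValueError, match="3 replicates"):
            ds.de_two_group(table)


class TestIntersect:
    @staticmethod
    def _table(up, down):
        genes = list(up) + list(down)
        return pd.DataFrame(
            {"direction": ["up"] * len(up) + ["down"] * len(down)},
            index=pd.Index(genes, name="gene_id"),
        )

    def test_hand_worked_example(self):
        a = self._table(["g1", "g2", "g3"], ["g4"])
        b = self._table(["g2", "g3", "g5"], ["g4", "g6"])
        up, down, counts = ds.intersect_signatures(a, b)
        assert counts == {"n_common_up": 2, "n_common_down": 1}
        assert up == ["g2", "g3"] and down == ["g4"]

    def test_disjoint_and_idempotent(self):
        a = self._table(["g1"], ["g2"])
        b = self._table(["h1"], ["h2"])
        _, _, counts = ds.intersect_signatures(a, b)
        assert counts == {"n_common_up": 0, "n_common_down": 0}
        _, _, same = ds.intersect_signatures(a, a)
        assert same == {"n_common_up": 1, "n_common_down": 1}

    def test_opposite_directions_excluded(self):
        a = self._table(["g1"], [])
        b = self._table([], ["g1"])
        up, down, counts = ds.intersect_signatures(a, b)
        assert counts == {"n_common_up": 0, "n_common_down": 0}


def test_alias_resolution_table():
    present, missing, applied = resolve_module_genes(
        ["SSEA1", "PROM1", "NOPE"], ["FUT4", "PROM1", "CD44"]
    )
    assert present == ["FUT4", "PROM1"]
    assert missing == ["NOPE"]
    assert applied == {"SSEA1": "FUT4"}
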