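"""Differential expression, rank tests, resampling nulls and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import synpid as sp


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(sp.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                    [0.04, 0.04, 0.04, 0.04])

    def test_two_values_by_hand(self):
        np.testing.assert_allclose(sp.bh_adjust([0.005, 0.5]), [0.01, 0.5])

    def test_single_p_unchanged(self):
        assert sp.bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        assert np.all(sp.bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sp.bh_adjust([0.5, 1.5])


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, p = sp.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(12 / 42 * 13.5, abs=1e-9)  # = 3.857...
        assert p == pytest.approx(scipy.stats.chi2.sf(h, 1), abs=1e-12)

    def test_identical_groups_degenerate(self):
        assert sp.kruskal_wallis([[2, 2], [2, 2, 2]]) == (0.0, 1.0)

    def test_within_group_order_invariance(self):
        _, p1 = sp.kruskal_wallis([[3, 1, 2], [9, 7, 8]])
        _, p2 = sp.kruskal_wallis([[1, 2, 3], [7, 8, 9]])
        assert p1 == p2

    def test_matches_first_principles_rank_statistic(self):
        """H agrees with an independent tie-corrected rank computation."""

        def h_by_hand(groups):
            pooled = np.concatenate(groups)
            order = np.argsort(pooled, kind="stable")
            ranks = np.empty(pooled.size)
            # average ranks for ties
            sorted_vals = pooled[order]
            i = 0
            while i < pooled.size:
                j = i
                while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            n = pooled.size
            start = 0
            h = 0.0
            for g in groups:
                r = ranks[start:start + len(g)]
                h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
                start += len(g)
            h *= 12.0 / (n * (n + 1))
            _, counts = np.unique(pooled, return_counts=True)
            tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
            return h / tie

        rng = np.random.default_rng(12)
        for _ in range(10):
            groups = [rng.integers(0, 5, size=rng.integers(2, 4)).astype(float)
                      for _ in range(rng.integers(2, 4))]
            if np.all(np.concatenate(groups) == np.concatenate(groups)[0]):
                continue
            h, _ = sp.kruskal_wallis(groups)
            assert h == pytest.approx(h_by_hand(groups), abs=1e-9)


class TestDGE:
    @pytest.mark.parametrize("lfc, adj_p, expected", [
        (2.0, 0.005, True),
        (1.6, 0.02, False),
        (1.0, 0.001, False),
    ])
    def test_double_threshold(self, lfc, adj_p, expected):
        flagged = abs(lfc) > 1.5 and adj_p < 0.01
        assert flagged is expected

    def test_identical_classes_not_flagged(self, small_community):
        expr, _ = small_community
        mat = expr.matrix.copy()
        mat.iloc[:, 30:] = mat.iloc[:, :30].to_numpy()  # mirror classes
        mirrored = sp.ExpressionCommunity(
            matrix=mat + np.random.default_rng(0).normal(0, 1e-9, mat.shape),
            class_labels=expr.class_labels, case_label="case")
        tab = sp.dge_test(mirrored)
        assert tab.log_fold_change.abs().max() < 1e-6
        assert not tab.is_differential.any()

    def test_planted_shift_recovered_null_controlled(self):
        expr, truth = sp.generate_expression_study(
            n_genes=500, n_case=50, n_control=50, n_de=10, effect_size=2.0,
            seed=5, gene_structure="independent")
        tab = sp.dge_test(expr)
        flagged = set(tab.index[tab.is_differential])
        assert flagged >= set(truth.planted_de_genes)
        assert len(flagged - set(truth.planted_de_genes)) <= 5  # BH at 1% of 500

    def test_shift_invariance_and_gene_order(self, small_community):
        expr, _ = small_community
        t1 = sp.dge_test(expr)
        shifted = sp.ExpressionCommunity(matrix=expr.matrix + 3.0,
                                         class_labels=expr.class_labels,
                                         case_label="case")
        t2 = sp.dge_test(shifted)
        pd.testing.assert_series_equal(t1.is_differential, t2.is_differential)
        perm = expr.matrix.sample(frac=1, random_state=1)
        t3 = sp.dge_test(sp.ExpressionCommunity(matrix=perm,
                                                class_labels=expr.class_labels,
                                                case_label="case"))
        assert set(t3.index[t3.is_differential]) == set(t1.index[t1.is_differential])

    def test_single_class_subset_rejected(self, small_community):
        expr, _ = small_community
        cases = [s for s in expr.sample_ids if expr.class_labels[s] == "case"]
        with pytest.raises(ValueError, match="contrast undefined"):
            sp.dge_test(expr, cases)


class TestEmpiricalPValues:
    def test_conventions_and_determinism(self, small_community):
        expr, _ = small_community
        cluster = expr.sample_ids[:10] + expr.sample_ids[30:40]
        t1 = sp.empirical_pvalues(expr, cluster, B=50, seed=3)
        t2 = sp.empirical_pvalues(expr, cluster, B=50, seed=3)
        pd.testing.assert_frame_equal(t1, t2)
        assert ((0 < t1.empirical_p) & (t1.empirical_p <= 1)).all()
        np.testing.assert_allclose(t1.empirical_p, (t1.exceed_count + 1) / 51)

    def test_degenerate_cluster_rejected(self, small_community):
        expr, _ = small_community
        with pytest.raises(ValueError, match="null degenerate"):
            sp.empirical_pvalues(expr, expr.sample_ids, B=10)

    def test_null_uniformity(self):
        expr, _ = sp.generate_expression_study(
            n_genes=200, n_case=50, n_control=50, n_de=0, effect_size=0.0,
            seed=11, gene_structure="independent")
        cluster = expr.sample_ids[:20] + expr.sample_ids[50:70]
        tab = sp.empirical_pvalues(expr, cluster, B=200, seed=3)
        assert scipy.stats.kstest(tab.empirical_p, "uniform").pvalue > 0.01


class TestBootstrap:
    def test_shapes_and_universe(self):
        genes = [f"g{i}" for i in range(40)]
        sets = sp.bootstrap_communities(genes, n_boot=10, seed=1)
        assert len(sets) == 10
        for s in sets:
            assert set(s) <= set(genes)
            assert len(s) == len(set(s))

    def test_seed_determinism(self):
        genes = [f"g{i}" for i in range(20)]
        assert sp.bootstrap_communities(genes, seed=7) == sp.bootstrap_communities(genes, seed=7)

    def test_unique_fraction_near_632(self):
        genes = [f"g{i}" for i in range(40)]
        fracs = [len(s) / 40
                 for seed in range(40)
                 for s in sp.bootstrap_communities(genes, n_boot=5, seed=seed)]
        assert np.mean(fracs) == pytest.approx(1 - (1 - 1 / 40) ** 40, abs=0.01)


class TestORA:
    def test_exact_tail_example(self):
        universe = [f"g{i}" for i in range(20)]
        gene_sets = {"S": universe[:5]}
        cluster = universe[:4] + [universe[10]]
        tab = sp.ora_hypergeometric(cluster, gene_sets, universe)
        assert tab.loc["S", "raw_p"] == pytest.approx(76 / 15504, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        tab = sp.ora_hypergeometric(universe[10:15], {"S": universe[:5]}, universe)
        assert tab.loc["S", "raw_p"] == 1.0

    def test_bonferroni_single_set_unchanged(self):
        universe = [f"g{i}" for i in range(20)]
        tab = sp.ora_hypergeometric(universe[:4], {"S": universe[:5]}, universe,
                                    correction="bonferroni")
        assert tab.loc["S", "corrected_p"] == tab.loc["S", "raw_p"]

    def test_matches_fisher_exact_oracle(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(60)]
        gene_sets = {f"S{j}": rng.choice(universe, size=12, replace=False).tolist()
                     for j in range(5)}
        cluster = rng.choice(universe, size=15, replace=False).tolist()
        tab = sp.ora_hypergeometric(cluster, gene_sets, universe)
        for name, genes in gene_sets.items():
            overlap = len(set(cluster) & set(genes))
            table = [[overlap, len(genes) - overlap],
                     [len(cluster) - overlap, 60 - len(genes) - len(cluster) + overlap]]
            _, fisher_p = scipy.stats.fisher_exact(table, alternative="greater")
            assert tab.loc[name, "raw_p"] == pytest.approx(fisher_p, rel=1e-9)

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            sp.ora_hypergeometric(["x"], {"S": ["a"]}, ["a", "b"])


def test_read_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("pathA\tdesc\tg1\tg2\tg3\npathB\t-\tg2\tg4\n")
    sets = sp.read_gmt(path)
    assert sets == {"pathA": ["g1", "g2", "g3"], "pathB": ["g2", "g4"]}
    with pytest.raises(ValueError, match="malformed"):
        bad = tmp_path / "bad.gmt"
        bad.write_text("onlyname\n")
        sp.read_gmt(bad)
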