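"""Statistics tests: bimodality metrics, Kruskal-Wallis, enrichment, Geary C'."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from scsplice import stats
from scsplice.cohort import simulate_trajectory_panel
from scsplice.stats import (
    _geary_score,
    _knn_weights,
    autocorrelation_test,
    binary_metrics,
    bimodality_flag,
    compute_embedding,
    evaluate_filter_enrichment,
    kruskal_wallis_by_cluster,
    normalize_psi_per_cell,
)


class TestBinaryMetrics:
    def test_hand_counted_proportions(self):
        psi = pd.DataFrame(
            {
                "all_binary": [0.0, 0.0, 1.0, 1.0],
                "mixed": [0.0, 0.5, 1.0, np.nan],
                "empty": [np.nan] * 4,
            },
            index=list("abcd"),
        )
        rep = binary_metrics(psi)
        assert rep.exon_binary_proportion["all_binary"] == 1.0
        assert rep.exon_binary_proportion["mixed"] == pytest.approx(2 / 3)
        assert np.isnan(rep.exon_binary_proportion["empty"])
        assert rep.cell_binary_proportion["a"] == 1.0  # two binary of two observed

    def test_intermediate_window(self):
        psi = pd.DataFrame({"low": [0.05] * 4, "mid": [0.5] * 4})
        rep = binary_metrics(psi)
        assert not rep.exon_intermediate["low"]
        assert rep.exon_intermediate["mid"]


class TestBimodalityFlag:
    def test_extreme_case_true(self):
        assert bimodality_flag(np.array([0.0, 0.0, 1.0, 1.0]))

    def test_constant_intermediate_false(self):
        assert not bimodality_flag(np.array([0.5] * 10))

    def test_insufficient_high_tail_false(self):
        v = np.array([0.1] * 30 + [0.9] * 20 + [0.5] * 50) / 1.0
        assert not bimodality_flag(v)

    def test_requires_observations(self):
        with pytest.raises(ValueError):
            bimodality_flag(np.array([np.nan]))


class TestKruskalWallis:
    def test_identical_values_defined_as_one(self):
        psi = pd.DataFrame({"e": [0.5] * 6})
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=psi.index)
        assert kruskal_wallis_by_cluster(psi, labels)["e"] == 1.0

    def test_separated_clusters_significant_and_match_rank_oracle(self):
        vals = [0.1, 0.2, 0.1, 0.8, 0.9, 0.9]
        psi = pd.DataFrame({"e": vals})
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=psi.index)
        p = kruskal_wallis_by_cluster(psi, labels)["e"]
        # hand rank-sum oracle: ranks of group a are {1.5, 1.5, 3}, n=6
        ranks = sps.rankdata(vals)
        h = 12 / (6 * 7) * (
            3 * (ranks[:3].mean() - 3.5) ** 2 + 3 * (ranks[3:].mean() - 3.5) ** 2
        )
        ties = [2, 2]  # two pairs of tied values
        h /= 1 - sum(t**3 - t for t in ties) / (6**3 - 6)
        assert p == pytest.approx(sps.chi2.sf(h, df=1), rel=1e-9)
        assert p < 0.05

    def test_small_clusters_excluded(self):
        psi = pd.DataFrame({"e": [0.1, 0.2, 0.9, np.nan, 0.5, 0.6]})
        labels = pd.Series(["a", "a", "b", "b", "c", "c"], index=psi.index)
        # cluster b has one observation: dropped, test runs on a vs c
        p = kruskal_wallis_by_cluster(psi, labels)["e"]
        assert np.isfinite(p)
        only_two = kruskal_wallis_by_cluster(
            psi.iloc[[0, 1, 2, 3]], labels.iloc[[0, 1, 2, 3]]
        )["e"]
        assert np.isnan(only_two)

    def test_null_pvalues_uniform(self, rng):
        n_cells, n_exons = 60, 500
        psi = pd.DataFrame(rng.beta(3, 3, size=(n_cells, n_exons)))
        labels = pd.Series(rng.integers(0, 3, n_cells), index=psi.index)
        pvals = kruskal_wallis_by_cluster(psi, labels).dropna()
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestEnrichment:
    def _uniform_universe(self, n=100, sig=20, seed=0):
        rng = np.random.default_rng(seed)
        pv = np.concatenate([rng.uniform(0, 0.05, sig), rng.uniform(0.051, 1, n - sig)])
        return pd.Series(pv, index=[f"e{i}" for i in range(n)])

    def test_fold_hand_value(self):
        pv = self._uniform_universe(100, 20)
        selected = set(pv.index[:12]) | set(pv.index[-18:])  # 12 significant of 30
        res = [r for r in evaluate_filter_enrichment(pv, selected) if r.p_threshold == 0.05]
        r = res[0]
        assert (r.universe_size, r.significant, r.selected, r.selected_significant) == (
            100,
            20,
            30,
            12,
        )
        assert r.fold == pytest.approx((100 * 12) / (30 * 20))
        assert r.pvalue == pytest.approx(sps.hypergeom.sf(11, 100, 20, 30))

    def test_selecting_everything_gives_fold_one(self):
        pv = self._uniform_universe()
        res = evaluate_filter_enrichment(pv, set(pv.index))
        for r in res:
            if r.significant > 0:
                assert r.fold == pytest.approx(1.0)

    def test_confusion_matrix_identities(self):
        pv = self._uniform_universe(80, 15, seed=3)
        selected = set(pv.index[::3])
        for r in evaluate_filter_enrichment(pv, selected):
            if r.significant == 0 or r.selected == 0:
                continue
            assert r.precision * r.selected == pytest.approx(r.selected_significant)
            assert r.recall * r.significant == pytest.approx(r.selected_significant)
            assert 0 <= r.f1 <= 1

    def test_perfect_selection(self):
        pv = self._uniform_universe(50, 10, seed=5)
        selected = set(pv.index[pv <= 0.05])
        res = [r for r in evaluate_filter_enrichment(pv, selected) if r.p_threshold == 0.05]
        assert res[0].precision == 1.0 and res[0].recall == 1.0


class TestGearyScore:
    def test_three_cell_hand_oracle(self):
        # cells on a line at x = 0, 1, 3; K = 1 nearest neighbor
        emb = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        w = _knn_weights(emb, 1)
        e1 = math.exp(-1.0)
        assert w[0, 1] == pytest.approx(e1) and w[1, 0] == pytest.approx(e1)
        assert w[2, 1] == pytest.approx(math.exp(-4.0 / 4.0))
        assert w[0, 2] == w[1, 2] == w[2, 0] == 0.0
        v = np.array([0.0, 1.0, 2.0])
        # brute-force double sum
        n = 3
        num = sum(
            w[j, k] * (v[j] - v[k]) ** 2 for j in range(n) for k in range(n)
        )
        den = 2 * w.sum() * ((v - v.mean()) ** 2).sum()
        expected = 1 - (n - 1) * num / den
        assert _geary_score(v, w) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(30, 2))
        w = _knn_weights(emb, 15)
        v = rng.uniform(size=30)
        assert _geary_score(v, w) == pytest.approx(_geary_score(10 * v, w), abs=1e-12)

    def test_missing_and_constant_values_undefined(self):
        emb = np.random.default_rng(0).normal(size=(10, 2))
        w = _knn_weights(emb, 5)
        v = np.full(10, np.nan)
        v[:2] = 0.5
        assert np.isnan(_geary_score(v, w))  # < 3 observed cells
        assert np.isnan(_geary_score(np.full(10, 0.3), w))  # zero variance

    def test_normalization_choice_cancels_in_score(self):
        rng = np.random.default_rng(4)
        psi = pd.DataFrame(rng.beta(2, 2, size=(40, 12)))
        emb = rng.normal(size=(40, 2))
        w = _knn_weights(emb, 20)
        by_var = normalize_psi_per_cell(psi, "variance").to_numpy()
        by_sd = normalize_psi_per_cell(psi, "sd").to_numpy()
        for j in range(psi.shape[1]):
            # per-cell scaling differs between the two conventions, but the
            # score is invariant to global scaling; check they stay close
            s1, s2 = _geary_score(by_var[:, j], w), _geary_score(by_sd[:, j], w)
            assert np.isfinite(s1) and np.isfinite(s2)


class TestAutocorrelationTest:
    def test_planted_smooth_detected_and_scrambled_not(self):
        panel = simulate_trajectory_panel(
            n_cells=80, n_smooth=10, n_scrambled=60, seed=2
        )
        emb = compute_embedding(panel.expression)
        res = autocorrelation_test(panel.psi, emb, n_perm=500, rng_seed=0)
        pv = pd.Series({r.exon_id: r.pvalue for r in res})
        smooth = panel.smooth[panel.smooth].index
        scrambled = panel.smooth[~panel.smooth].index
        assert (pv[smooth] < 0.05).mean() > 0.8
        assert (pv[scrambled] < 0.05).mean() < 0.2

    def test_minimum_pvalue_is_one_over_nperm_plus_one(self):
        panel = simulate_trajectory_panel(n_cells=60, n_smooth=5, n_scrambled=30, seed=9)
        emb = compute_embedding(panel.expression)
        res = autocorrelation_test(panel.psi, emb, n_perm=200, rng_seed=1)
        pv = np.array([r.pvalue for r in res])
        assert pv.min() == pytest.approx(1 / 201)

    def test_reproducible_with_seed(self):
        panel = simulate_trajectory_panel(n_cells=50, n_smooth=3, n_scrambled=20, seed=4)
        emb = compute_embedding(panel.expression)
        a = autocorrelation_test(panel.psi, emb, n_perm=100, rng_seed=7)
        b = autocorrelation_test(panel.psi, emb, n_perm=100, rng_seed=7)
        assert [r.pvalue for r in a] == [r.pvalue for r in b]


class TestEmbedding:
    def test_duplicate_cells_identical_coordinates(self, rng):
        x = rng.poisson(5, size=(10, 20)).astype(float)
        x[3] = x[0]
        emb = compute_embedding(x)
        assert np.allclose(emb[0], emb[3])

    def test_disjoint_programs_separate(self, rng):
        a = np.hstack([rng.poisson(20, size=(15, 30)), np.zeros((15, 30))])
        b = np.hstack([np.zeros((15, 30)), rng.poisson(20, size=(15, 30))])
        emb = compute_embedding(np.vstack([a, b]))
        from sklearn.metrics import silhouette_score

        labels = [0] * 15 + [1] * 15
        assert silhouette_score(emb, labels) > 0.5

    def test_single_varying_gene_orders_cells(self, rng):
        base = np.full((20, 5), 50.0)
        base[:, 0] = np.arange(20) * 100 + 10
        emb = compute_embedding(base)
        rho = sps.spearmanr(emb[:, 0], np.arange(20)).statistic
        assert abs(rho) > 0.99

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_embedding(np.ones((5, 4)))
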