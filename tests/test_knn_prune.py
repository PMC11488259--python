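import numpy as np
import pytest
from scipy import stats

from metagrn.data_io import CountMatrix, Embedding
from metagrn import knn_prune
from metagrn.knn_prune import (
    KnnGraph,
    LinkProbMatrix,
    build_knn,
    fit_local_background,
    gene_count_probability,
    link_probabilities,
    prune_graph,
)


def _embedding(coords):
    coords = np.asarray(coords, dtype=float)
    return Embedding(coords=coords, eigenvalues=np.ones(coords.shape[1]))


class TestBuildKnn:
    def test_collinear_points(self):
        emb = _embedding([[0.0], [1.0], [3.0]])
        graph = build_knn(emb, K=1)
        assert graph.neighbors[:, 0].tolist() == [1, 0, 1]

    def test_distances_non_decreasing(self, rng):
        emb = _embedding(rng.normal(size=(40, 3)))
        graph = build_knn(emb, K=6)
        assert np.all(np.diff(graph.distances, axis=1) >= -1e-12)

    def test_matches_brute_force(self, rng):
        coords = rng.normal(size=(50, 4))
        graph = build_knn(_embedding(coords), K=5)
        for j in range(50):
            d = np.linalg.norm(coords - coords[j], axis=1)
            d[j] = np.inf
            expected = np.lexsort((np.arange(50), d))[:5]
            assert graph.neighbors[j].tolist() == expected.tolist()

    def test_invalid_k(self, rng):
        emb = _embedding(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            build_knn(emb, K=0)
        with pytest.raises(ValueError):
            build_knn(emb, K=10)


def _counts_and_graph(values, K=3):
    values = np.asarray(values)
    cm = CountMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"c{i}" for i in range(values.shape[1])],
    )
    m = values.shape[1]
    neighbors = np.array([[j for j in range(m) if j != i][:K] for i in range(m)])
    graph = KnnGraph(neighbors=neighbors, distances=np.ones_like(neighbors, float))
    return cm, graph


class TestLocalBackground:
    def test_identical_columns_near_poisson(self, rng):
        col = rng.integers(1, 20, size=10)
        cm, graph = _counts_and_graph(np.column_stack([col] * 5))
        model = fit_local_background(cm, graph, 0)
        assert np.allclose(model.mu, col)
        assert np.all(model.r[model.mu > 0] > 1e4)  # variance clipped to ~mu

    def test_mu_linear_in_depth(self, rng):
        values = rng.integers(0, 12, size=(8, 5)) + 1
        cm1, graph = _counts_and_graph(values)
        cm2, _ = _counts_and_graph(values * 2)
        m1 = fit_local_background(cm1, graph, 0)
        m2 = fit_local_background(cm2, graph, 0)
        assert np.allclose(m2.mu, 2 * m1.mu)

    def test_variance_fit_matches_polyfit_oracle(self, rng):
        values = rng.negative_binomial(5, 0.3, size=(30, 6))
        cm, graph = _counts_and_graph(values, K=5)
        model = fit_local_background(cm, graph, 0)
        cols = values.astype(float)
        libs = cols.sum(axis=0)
        scaled = cols * (np.median(libs) / libs)
        mu = scaled.mean(axis=1)
        var = scaled.var(axis=1, ddof=1)
        ok = (mu > 0) & (var > 0)
        coeffs = np.polyfit(np.log(mu[ok]), np.log(var[ok]), 2)
        assert np.allclose(model.poly_coeffs, coeffs)

    def test_zero_neighborhood_error(self):
        cm, graph = _counts_and_graph(np.zeros((4, 5), dtype=int))
        with pytest.raises(ValueError, match="zero total"):
            fit_local_background(cm, graph, 0)


class TestGeneCountProbability:
    def test_median_count_probability_near_one(self, rng):
        values = rng.poisson(10, size=(6, 8))
        cm, graph = _counts_and_graph(values, K=7)
        model = fit_local_background(cm, graph, 0)
        med = int(stats.nbinom.median(min(model.r[0], 1e12), min(model.r[0], 1e12) / (min(model.r[0], 1e12) + model.mu[0])))
        p = gene_count_probability(model, 0, med)
        assert p > 0.5

    def test_poisson_tail_oracle(self):
        # mu=5, r -> infinity reduces to Poisson; x=50 is far in the tail
        model = knn_prune.LocalNbModel(
            mu=np.array([5.0]),
            r=np.array([np.inf]),
            poly_coeffs=np.zeros(3),
            members=np.arange(4),
            median_library=1.0,
        )
        p = gene_count_probability(model, 0, 50)
        upper = 1.0 - stats.poisson.cdf(49, 5.0)  # oracle: summed Poisson pmf
        assert p < 1e-10
        assert p == pytest.approx(2 * upper, rel=1e-6)

    def test_monotone_above_mode(self):
        model = knn_prune.LocalNbModel(
            mu=np.array([8.0]),
            r=np.array([4.0]),
            poly_coeffs=np.zeros(3),
            members=np.arange(4),
            median_library=1.0,
        )
        probs = [gene_count_probability(model, 0, x) for x in range(10, 60)]
        assert np.all(np.diff(probs) <= 1e-15)

    @pytest.mark.parametrize("mu,r", [(0.5, 1.0), (5.0, 2.0), (20.0, 50.0)])
    def test_agrees_with_pmf_summation(self, mu, r):
        model = knn_prune.LocalNbModel(
            mu=np.array([mu]),
            r=np.array([r]),
            poly_coeffs=np.zeros(3),
            members=np.arange(4),
            median_library=1.0,
        )
        p_nb = r / (r + mu)
        pmf = stats.nbinom.pmf(np.arange(0, 1001), r, p_nb)
        for x in [0, 1, 2, 5, 10, 50, 200]:
            lower = pmf[: x + 1].sum()
            upper = pmf[x:].sum()
            expected = min(1.0, 2.0 * min(lower, upper))
            assert gene_count_probability(model, 0, x) == pytest.approx(
                expected, abs=1e-10
            )


class TestLinkProbabilities:
    def test_geometric_mean_arithmetic(self):
        assert (0.1 * 0.2 * 0.5) ** (1 / 3) == pytest.approx(0.21544, abs=1e-4)

    def test_matches_per_gene_enumeration(self, rng):
        values = rng.negative_binomial(4, 0.4, size=(10, 6))
        values[:, 0] += 1
        cm, graph = _counts_and_graph(values, K=4)
        lp = link_probabilities(cm, graph, cells=np.array([0]))
        model = fit_local_background(cm, graph, 0)
        cols = values[:, graph.neighbors[0]].astype(float)
        libs = cols.sum(axis=0)
        x = np.rint(cols * (model.median_library / libs)).astype(int)
        for l in range(4):
            per_gene = np.array(
                [gene_count_probability(model, g, int(x[g, l])) for g in range(10)]
            )
            three = np.sort(per_gene)[:3]
            expected = np.exp(np.mean(np.log(np.maximum(three, 1e-300))))
            assert lp.probs[l, 0] == pytest.approx(expected, rel=1e-9)

    def test_few_genes_warns(self, rng):
        values = rng.integers(1, 9, size=(2, 5))
        cm, graph = _counts_and_graph(values, K=3)
        with pytest.warns(UserWarning, match="genes"):
            link_probabilities(cm, graph, cells=np.array([0]))


class TestPruneGraph:
    def _probs(self, vals):
        probs = np.asarray(vals, dtype=float)[:, None]
        cells = np.array([0])
        m = probs.shape[0] + 1
        neighbors = np.tile(np.arange(1, probs.shape[0] + 1), (m, 1))
        graph = KnnGraph(neighbors=neighbors, distances=np.ones_like(neighbors, float))
        return LinkProbMatrix(probs=probs, cells=cells), graph

    def test_zero_threshold_prunes_nothing(self):
        lp, graph = self._probs([0.005, 0.02, 0.5])
        pruned = prune_graph(lp, graph, p_tr=0.0)
        assert len(pruned.neighbors[0]) == 3

    def test_threshold_rule(self):
        lp, graph = self._probs([0.005, 0.02, 0.5])
        pruned = prune_graph(lp, graph, p_tr=0.01)
        assert pruned.neighbors[0].tolist() == [2, 3]

    def test_surviving_count_conservation(self, rng):
        vals = rng.random(10)
        lp, graph = self._probs(vals)
        pruned = prune_graph(lp, graph, p_tr=0.3)
        assert len(pruned.neighbors[0]) == int((vals >= 0.3).sum())

    def test_invalid_threshold(self):
        lp, graph = self._probs([0.5])
        with pytest.raises(ValueError):
            prune_graph(lp, graph, p_tr=1.5)

    def test_all_surviving_links_above_threshold(self, mini_pipeline):
        pruned = mini_pipeline["pruned"]
        for pr in pruned.probs:
            assert np.all(pr >= pruned.p_tr)


def test_cross_population_links_less_probable():
    """Two NB populations with a 4-fold mean shift in 50 genes: links that
    cross populations get lower probabilities than links within."""
    rng = np.random.default_rng(7)
    n_genes, n_per = 50, 30
    base = rng.gamma(2.0, 2.0, size=n_genes) + 0.5
    shifted = base.copy()
    shifted[:50] *= 4.0
    pop1 = rng.negative_binomial(5, 5 / (5 + base[:, None]), size=(n_genes, n_per))
    pop2 = rng.negative_binomial(5, 5 / (5 + shifted[:, None]), size=(n_genes, n_per))
    cm = CountMatrix(
        np.concatenate([pop1, pop2], axis=1),
        [f"g{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(2 * n_per)],
    )
    # mixed neighborhood: each cell's neighbor list spans both populations
    K = 10
    neighbors = np.zeros((2 * n_per, K), dtype=int)
    for j in range(2 * n_per):
        within = [i for i in range(n_per) if (i + (j // n_per) * n_per) != j]
        cross = list(range(n_per, 2 * n_per) if j < n_per else range(n_per))
        neighbors[j] = [i + (j // n_per) * n_per for i in within[: K // 2]] + cross[: K // 2]
    graph = KnnGraph(neighbors=neighbors, distances=np.ones_like(neighbors, float))
    lp = link_probabilities(cm, graph, cells=np.arange(2 * n_per))
    same_pop = (neighbors < n_per) == (np.arange(2 * n_per)[:, None] < n_per)
    within_probs = lp.probs.T[same_pop]
    cross_probs = lp.probs.T[~same_pop]
    assert np.median(cross_probs) < np.median(within_probs)
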