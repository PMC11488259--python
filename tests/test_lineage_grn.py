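import numpy as np
import pytest

from metagrn.grn_core import SkeletonNetwork
from metagrn.knn_prune import PrunedKnnGraph
from metagrn.lineage_grn import (
    FateMatrix,
    LineageSeries,
    _biased_fates,
    cluster_fates,
    fit_granger,
    granger_edge_weights,
    infer_lineage_grn,
    markov_fate_probabilities,
    metacell_fate_probabilities,
    order_lineage_metacells,
    rank_transform,
)
from metagrn.metacell import MetacellMatrix


def _metacells(values):
    values = np.asarray(values)
    return MetacellMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        seed_cells=np.arange(values.shape[1]),
        member_lists=[np.array([j]) for j in range(values.shape[1])],
        min_partners=0,
    )


class TestMetacellFates:
    def test_mean_of_members(self):
        fates = FateMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ["a", "b"])
        out = metacell_fate_probabilities(fates, [np.array([0, 1])])
        assert out.probs[0].tolist() == [0.5, 0.5]

    def test_single_member_identity(self):
        fates = FateMatrix(np.array([[0.3, 0.7], [0.9, 0.1]]), ["a", "b"])
        out = metacell_fate_probabilities(fates, [np.array([1])])
        assert out.probs[0] == pytest.approx([0.9, 0.1])

    def test_rows_renormalized(self, rng):
        fates = FateMatrix(rng.dirichlet([1, 1, 1], size=10), ["a", "b", "c"])
        out = metacell_fate_probabilities(
            fates, [np.array([0, 3, 5]), np.array([1, 2])]
        )
        assert np.allclose(out.probs.sum(axis=1), 1.0)

    def test_empty_metacell_error(self):
        fates = FateMatrix(np.array([[0.5, 0.5]]), ["a", "b"])
        with pytest.raises(ValueError):
            metacell_fate_probabilities(fates, [np.array([], dtype=int)])


class TestBiasRule:
    def test_nine_fold_dominance(self):
        assert _biased_fates(np.array([0.9, 0.1]), 2.0) == (0,)
        assert _biased_fates(np.array([0.1, 0.9]), 2.0) == (1,)

    def test_balanced_is_uncertain(self):
        assert _biased_fates(np.array([0.5, 0.5]), 2.0) == ()

    def test_biased_subset(self):
        # 0.45 >= 2 x 0.10 holds for both leading fates, but neither
        # dominates the other -> assigned to the pair
        assert _biased_fates(np.array([0.45, 0.45, 0.10]), 2.0) == (0, 1)

    def test_no_clean_split_is_uncertain(self):
        assert _biased_fates(np.array([0.5, 0.3, 0.2]), 2.0) == ()


class TestClusterFates:
    def test_two_separated_clusters(self, rng):
        rows = np.vstack(
            [
                np.clip(rng.normal(0.9, 0.02, size=(40, 1)), 0, 1),
                np.clip(rng.normal(0.1, 0.02, size=(40, 1)), 0, 1),
            ]
        )
        fates = FateMatrix(np.column_stack([rows, 1 - rows]), ["f1", "f2"])
        out = cluster_fates(fates, fold_k=2.0, rng_seed=0)
        assert set(range(40)) <= set(out.lineage_members["f1"].tolist())
        assert set(range(40, 80)) <= set(out.lineage_members["f2"].tolist())
        assert not (
            set(range(40, 80)) & set(out.lineage_members["f1"].tolist())
        )

    def test_uncertain_cluster_joins_both(self, rng):
        rows = np.vstack(
            [
                np.clip(rng.normal(0.9, 0.02, size=(30, 1)), 0, 1),
                np.clip(rng.normal(0.5, 0.02, size=(30, 1)), 0, 1),
            ]
        )
        fates = FateMatrix(np.column_stack([rows, 1 - rows]), ["f1", "f2"])
        out = cluster_fates(fates, fold_k=2.0, rng_seed=0)
        mid = set(range(30, 60))
        assert mid <= set(out.lineage_members["f1"].tolist())
        assert mid <= set(out.lineage_members["f2"].tolist())

    def test_single_fate_rejected(self):
        with pytest.raises(ValueError):
            cluster_fates(FateMatrix(np.ones((5, 1)), ["only"]))


class TestOrdering:
    def _fates(self, p):
        p = np.asarray(p, dtype=float)
        return FateMatrix(np.column_stack([p, 1 - p]), ["f1", "f2"])

    def _assignment(self, n):
        from metagrn.lineage_grn import LineageAssignment

        return LineageAssignment(
            cluster_of=np.zeros(n, dtype=int),
            cluster_fates={0: ()},
            lineage_members={"f1": np.arange(n), "f2": np.arange(n)},
            uncertain=np.arange(n),
            fold_k=2.0,
            n_components=1,
            bic_trace=np.zeros(1),
        )

    def test_sorted_by_probability(self, rng):
        mc = _metacells(rng.integers(1, 9, size=(4, 3)))
        series = order_lineage_metacells(
            mc, self._fates([0.2, 0.9, 0.5]), self._assignment(3), "f1"
        )
        assert series.metacell_order.tolist() == [0, 2, 1]

    def test_tie_broken_by_index(self, rng):
        mc = _metacells(rng.integers(1, 9, size=(4, 2)))
        series = order_lineage_metacells(
            mc, self._fates([0.5, 0.5]), self._assignment(2), "f1"
        )
        assert series.metacell_order.tolist() == [0, 1]

    def test_length_equals_lineage_size(self, rng):
        mc = _metacells(rng.integers(1, 9, size=(4, 6)))
        series = order_lineage_metacells(
            mc, self._fates(rng.random(6)), self._assignment(6), "f1"
        )
        assert series.T == 6


def _series(expr, gene_ids):
    expr = np.asarray(expr, dtype=float)
    return LineageSeries(
        expression=expr,
        gene_ids=gene_ids,
        metacell_order=np.arange(expr.shape[1]),
        fate_probability=np.linspace(0, 1, expr.shape[1]),
        lineage="f1",
    )


def _skeleton(regs, tgts, edges):
    adj = np.zeros((len(regs), len(tgts)), dtype=bool)
    for a, b in edges:
        adj[regs.index(a), tgts.index(b)] = True
    return SkeletonNetwork(adj, regs, tgts)


class TestFitGranger:
    def test_infinite_shrinkage_zeroes_coefficients(self, rng):
        expr = rng.normal(size=(2, 60))
        skel = _skeleton(["g0"], ["g0", "g1"], [("g0", "g1")])
        coeffs = fit_granger(
            _series(expr, ["g0", "g1"]), skel, "g1", L=3, lambda_reg=1e9
        )
        assert np.max(np.abs(coeffs.coeffs)) < 1e-4

    def test_noiseless_lag_one_recovered(self):
        rng = np.random.default_rng(3)
        T = 80
        x = rng.normal(size=T)
        # feed the model already-standardized series so the 0.8 carries
        # through the per-gene standardization unchanged
        xs = (x - x.mean()) / x.std()
        ys = 0.8 * np.concatenate([[0.0], xs[:-1]])
        ys = (ys - ys.mean()) / ys.std()
        skel = _skeleton(["g0"], ["g0", "g1"], [("g0", "g1")])
        coeffs = fit_granger(
            _series(np.vstack([xs, ys]), ["g0", "g1"]), skel, "g1", L=1, lambda_reg=0.0
        )
        # the fitted coefficient reproduces y from lagged x exactly
        resid = ys[1:] - coeffs.coeffs[0, 0] * xs[:-1] - coeffs.intercept
        assert np.max(np.abs(resid)) < 1e-8

    def test_matches_closed_form_oracle(self, rng):
        T, P, L, lam = 100, 3, 5, 150.0
        expr = rng.normal(size=(P + 1, T))
        genes = [f"g{i}" for i in range(P + 1)]
        skel = _skeleton(genes[:P], genes, [(g, genes[P]) for g in genes[:P]])
        coeffs = fit_granger(_series(expr, genes), skel, genes[P], L=L, lambda_reg=lam)
        # oracle: explicit lagged design + (X'X + lam I)^-1 X'y on the
        # centered, per-gene standardized series
        std = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)
        rows = T - L
        X = np.zeros((rows, P * L))
        for j in range(P):
            for l in range(1, L + 1):
                X[:, j * L + l - 1] = std[j, L - l : T - l]
        y = std[P, L:]
        Xc = X - X.mean(axis=0)
        a = np.linalg.solve(Xc.T @ Xc + lam * np.eye(P * L), Xc.T @ (y - y.mean()))
        assert np.allclose(coeffs.coeffs.ravel(), a, atol=1e-8)

    def test_group_penalty_matches_ridge_free_limit(self, rng):
        T, P, L = 60, 2, 2
        expr = rng.normal(size=(P + 1, T))
        genes = [f"g{i}" for i in range(P + 1)]
        skel = _skeleton(genes[:P], genes, [(g, genes[P]) for g in genes[:P]])
        series = _series(expr, genes)
        a_ols = fit_granger(series, skel, genes[P], L=L, lambda_reg=1e-8)
        a_grp = fit_granger(
            series, skel, genes[P], L=L, lambda_reg=1e-8, penalty="group"
        )
        assert np.allclose(a_ols.coeffs, a_grp.coeffs, atol=1e-4)

    def test_lag_reduced_for_short_series(self, rng):
        expr = rng.normal(size=(2, 20))
        skel = _skeleton(["g0"], ["g0", "g1"], [("g0", "g1")])
        coeffs = fit_granger(_series(expr, ["g0", "g1"]), skel, "g1", L=30)
        assert coeffs.L == (20 - 1) // 3

    def test_no_regulators_error(self, rng):
        expr = rng.normal(size=(2, 50))
        skel = _skeleton(["g0"], ["g0", "g1"], [])
        with pytest.raises(ValueError, match="no skeleton regulators"):
            fit_granger(_series(expr, ["g0", "g1"]), skel, "g1")


class TestEdgeWeightsAndRank:
    def _coeffs(self, rows):
        from metagrn.lineage_grn import GrangerCoeffs

        rows = np.asarray(rows, dtype=float)
        return GrangerCoeffs(
            coeffs=rows,
            regulators=[f"r{i}" for i in range(rows.shape[0])],
            target="t",
            lambda_reg=1.0,
            L=rows.shape[1],
        )

    def test_lag_sum_absolute(self):
        w = granger_edge_weights(self._coeffs([[0.5, -0.2, 0.1]]))
        assert w["r0"] == pytest.approx(0.4)

    def test_cancellation_inside_absolute(self):
        w = granger_edge_weights(self._coeffs([[0.5, -0.5]]))
        assert w["r0"] == 0.0

    def test_zero_coefficients(self):
        w = granger_edge_weights(self._coeffs([[0.0, 0.0]]))
        assert w["r0"] == 0.0

    def test_rank_transform_formula(self):
        out = rank_transform(np.array([[0.9, 0.5, 0.2]]))
        assert out[0].tolist() == [1.0, 0.25, pytest.approx(1 / 9)]

    def test_rank_transform_zero_row(self):
        out = rank_transform(np.zeros((1, 4)))
        assert np.all(out == 0)

    def test_rank_transform_tie_by_index(self):
        out = rank_transform(np.array([[0.5, 0.5]]))
        assert out[0].tolist() == [1.0, 0.25]

    def test_rank_values_exactly_inverse_squares(self, rng):
        G = rng.random((5, 12)) * (rng.random((5, 12)) < 0.6)
        out = rank_transform(G)
        for r in range(5):
            nonzero = sorted(out[r][out[r] > 0], reverse=True)
            expected = [1.0 / i**2 for i in range(1, len(nonzero) + 1)]
            assert nonzero == pytest.approx(expected)


class TestMarkovFates:
    def _chain(self, n):
        """Path graph 0-1-...-n-1 with unit link probabilities."""
        cells = np.arange(n)
        neighbors, probs = [], []
        for i in range(n):
            nb = [j for j in (i - 1, i + 1) if 0 <= j < n]
            neighbors.append(np.array(nb))
            probs.append(np.ones(len(nb)))
        return PrunedKnnGraph(cells=cells, neighbors=neighbors, probs=probs, p_tr=0.0)

    def test_terminal_rows_are_indicators(self):
        fates = markov_fate_probabilities(
            self._chain(5), {"left": [0], "right": [4]}
        )
        assert fates.probs[0].tolist() == [1.0, 0.0]
        assert fates.probs[4].tolist() == [0.0, 1.0]

    def test_rows_sum_to_one(self):
        fates = markov_fate_probabilities(self._chain(7), {"l": [0], "r": [6]})
        assert np.allclose(fates.probs.sum(axis=1), 1.0)

    def test_gamblers_ruin_oracle(self):
        # symmetric walk on a 5-node chain: absorption at the right end
        # from position i has probability i/4
        fates = markov_fate_probabilities(self._chain(5), {"l": [0], "r": [4]})
        assert np.allclose(fates.probs[:, 1], np.arange(5) / 4.0, atol=1e-10)

    def test_overlapping_terminals_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            markov_fate_probabilities(self._chain(5), {"l": [0], "r": [0, 4]})


def test_lineage_grn_rank_values(mini_pipeline):
    """End-to-end lineage network: G_tilde rows contain exactly the
    inverse-square rank values for each regulator's skeleton targets."""
    from metagrn import grn_core

    pp = mini_pipeline
    ds = pp["dataset"]
    mcs = pp["metacells"]
    grn = grn_core.infer_global_grn(mcs, ds.truth.tf_ids, n_trees=20, rng_seed=0)
    skel = grn_core.binarize_skeleton(grn, top_n=5)
    mcf = metacell_fate_probabilities(ds.fates, mcs.member_lists)
    la = cluster_fates(mcf, rng_seed=0)
    lg = infer_lineage_grn(mcs, mcf, la, skel, "CT1", L=5)
    for r in range(len(lg.regulator_ids)):
        degree = int(skel.adjacency[r].sum())
        values = sorted(lg.G_tilde[r][lg.G_tilde[r] > 0], reverse=True)
        assert values == pytest.approx([1.0 / i**2 for i in range(1, degree + 1)])
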