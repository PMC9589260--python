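import numpy as np
import pytest
from scipy.stats import pearsonr

from pdjdsnmf import (
    DeepFactorModel,
    LayerDims,
    OmicsMatrix,
    PDJDSNMF,
    PenaltyWeights,
    forward,
    objective,
    reconstruction_correlation,
    sigmoid,
    svd_init,
)
from pdjdsnmf.model import _layers, _objective_and_grads, gradients
from tests.conftest import make_omics


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == 0.5

    @pytest.mark.parametrize("x", [-5.0, -1.0, 2.0, 50.0])
    def test_complement_identity(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-15)

    def test_large_arguments_stable(self):
        # exp(710) overflows a float64; the stable form must not
        with np.errstate(over="raise"):
            hi = sigmoid(710.0)
            lo = sigmoid(-710.0)
        assert hi == 1.0
        assert 0.0 <= lo < 1e-300


class TestForward:
    def test_zero_junction_gives_half_layer(self, rng):
        n, k0, k1, p = 4, 3, 2, 5
        U = rng.normal(size=(n, k0))
        model = DeepFactorModel(
            U=U, Z=[[np.zeros((k0, k1))]], Hdeep=[rng.normal(size=(k1, p))],
            dims=LayerDims([k0, k1]),
        )
        H0, Xhat = forward(model, 0)
        np.testing.assert_array_equal(H0, np.full((k0, p), 0.5))
        np.testing.assert_allclose(Xhat, 0.5 * U @ np.ones((k0, p)))

    def test_two_sublayer_nesting_matches_hand_rolled(self):
        # k=[2,2,1], all-ones junctions and deep layer, single feature
        ones = np.ones
        model = DeepFactorModel(
            U=ones((3, 2)), Z=[[ones((2, 2)), ones((2, 1))]], Hdeep=[ones((1, 1))],
            dims=LayerDims([2, 2, 1]),
        )
        H0, _ = forward(model, 0)
        h1 = 1 / (1 + np.exp(-1.0))          # s(Z2 @ H2) elementwise
        expected = 1 / (1 + np.exp(-2 * h1))  # s(Z1 @ H1), Z1 row sums = 2*h1
        np.testing.assert_allclose(H0, np.full((2, 1), expected), rtol=1e-12)

    def test_layers_strictly_inside_unit_interval(self, rng):
        model = DeepFactorModel(
            U=rng.normal(size=(5, 3)),
            Z=[[rng.normal(size=(3, 2)) * 2]],
            Hdeep=[rng.normal(size=(2, 7)) * 2],
            dims=LayerDims([3, 2]),
        )
        H0, _ = forward(model, 0)
        assert H0.min() > 0.0 and H0.max() < 1.0

    def test_shape_mismatch_names_layer(self, rng):
        model = DeepFactorModel(
            U=rng.normal(size=(5, 3)), Z=[[rng.normal(size=(3, 3))]],
            Hdeep=[rng.normal(size=(2, 7))], dims=LayerDims([3, 2]),
        )
        with pytest.raises(ValueError, match="Z"):
            forward(model, 0)


class TestObjective:
    def test_penalty_free_total_is_pure_residual(self, small_trio, rng):
        X, P, graphs = small_trio
        model = svd_init(X, LayerDims([3, 2]), seed=0)
        w0 = PenaltyWeights(0.0, 0.0, 0.0)
        total, terms = objective(model, X, P, graphs, w0)
        resid = sum(
            np.sum((model.U @ forward(model, i)[0] - X[i].values) ** 2) for i in range(3)
        )
        assert total == pytest.approx(resid, rel=1e-12)
        assert terms[0] == pytest.approx(resid, rel=1e-12)

    def test_constant_rows_annihilate_graph_terms(self, small_trio, rng):
        X, P, graphs = small_trio
        # identical deep-layer columns make every H0 row constant across features
        Z = [[rng.normal(size=(3, 2))] for _ in range(3)]
        Hdeep = [np.tile(rng.normal(size=(2, 1)), (1, x.n_features)) for x in X]
        model = DeepFactorModel(U=rng.normal(size=(6, 3)), Z=Z, Hdeep=Hdeep,
                                dims=LayerDims([3, 2]))
        w = PenaltyWeights(0.0, 1.0, 1.0)
        _, terms = objective(model, X, P, graphs, w, ppi_mode="laplacian")
        assert terms[2] == pytest.approx(0.0, abs=1e-18)
        assert terms[3] == pytest.approx(0.0, abs=1e-18)

    def test_trace_terms_match_brute_force_pairwise_sum(self, small_trio, rng):
        X, P, graphs = small_trio
        model = svd_init(X, LayerDims([2, 2]), seed=0)
        for par in model.parameters():
            par += 0.2 * rng.normal(size=par.shape)
        w = PenaltyWeights(0.0, 1.0, 1.0)
        _, terms = objective(model, X, P, graphs, w, ppi_mode="laplacian")
        # laplacian term over all three graphs
        lap = 0.0
        for i, g in enumerate(graphs):
            H0 = forward(model, i)[0]
            A = g.connectivity
            for a in range(A.shape[0]):
                for b in range(A.shape[1]):
                    lap += 0.5 * A[a, b] * np.sum((H0[:, a] - H0[:, b]) ** 2)
        assert terms[3] == pytest.approx(lap, rel=1e-10)
        # ppi term against the same pairwise oracle on the prior adjacency
        H0 = forward(model, 0)[0]
        ppi = 0.0
        A = P.adjacency
        for a in range(A.shape[0]):
            for b in range(A.shape[1]):
                ppi += 0.5 * A[a, b] * np.sum((H0[:, a] - H0[:, b]) ** 2)
        assert terms[2] == pytest.approx(ppi, rel=1e-10)

    def test_graph_penalties_nonnegative_in_laplacian_mode(self, small_trio, rng):
        X, P, graphs = small_trio
        for seed in range(5):
            model = svd_init(X, LayerDims([3, 2]), seed=0)
            r = np.random.default_rng(seed)
            for par in model.parameters():
                par += r.normal(size=par.shape)
            _, terms = objective(model, X, P, graphs, PenaltyWeights(0, 1, 1))
            assert terms[2] >= 0.0 and terms[3] >= 0.0


class TestGradients:
    def test_matches_central_finite_differences(self, small_trio, rng):
        X, P, graphs = small_trio
        model = svd_init(X, LayerDims([3, 2]), seed=0)
        for par in model.parameters():
            par += 0.3 * rng.normal(size=par.shape)
        w = PenaltyWeights(0.01, 0.1, 0.05)
        g = gradients(model, X, P, graphs, w)
        h = 1e-6
        for pa, ga in zip(model.parameters(), g.parameters()):
            it = np.nditer(pa, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = pa[idx]
                pa[idx] = orig + h
                fp = _objective_and_grads(model, X, P, graphs, w, "laplacian", 0, False)[0]
                pa[idx] = orig - h
                fm = _objective_and_grads(model, X, P, graphs, w, "laplacian", 0, False)[0]
                pa[idx] = orig
                num = (fp - fm) / (2 * h)
                assert abs(num - ga[idx]) / max(abs(num), 1e-8) < 1e-4


class TestSvdInit:
    def test_deterministic(self, small_trio):
        X, _, _ = small_trio
        a = svd_init(X, LayerDims([3, 2]), seed=0)
        b = svd_init(X, LayerDims([3, 2]), seed=0)
        assert all(np.array_equal(x, y) for x, y in zip(a.parameters(), b.parameters()))

    def test_oversized_rank_rejected(self, small_trio):
        X, _, _ = small_trio
        with pytest.raises(ValueError, match="k0"):
            svd_init(X, LayerDims([7]), seed=0)

    def test_initialization_reconstructs_rank_k0_data(self, planted_noiseless):
        """On noiseless rank-k0 planted data the SVD start alone is already
        a good reconstruction (no training)."""
        X, _, _ = planted_noiseless
        model = svd_init(X, LayerDims([8, 6]), seed=0)
        corrs = [reconstruction_correlation(x, forward(model, i)[1]) for i, x in enumerate(X)]
        assert np.mean(corrs) >= 0.9


class TestReconstructionCorrelation:
    def test_identity_is_one(self, rng):
        X = make_omics(rng, 5, 4, "m")
        assert reconstruction_correlation(X, X.values) == pytest.approx(1.0)

    def test_negated_centered_is_minus_one(self, rng):
        X = make_omics(rng, 5, 4, "m")
        c = X.values - X.values.mean()
        assert reconstruction_correlation(
            OmicsMatrix(c, X.sample_ids, X.feature_ids), -c
        ) == pytest.approx(-1.0)

    def test_small_instance_matches_pearson(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        Y = np.array([[1.0, 2.0], [3.0, 5.0]])
        expected = pearsonr(X.ravel(), Y.ravel()).statistic
        assert reconstruction_correlation(X, Y) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            reconstruction_correlation(np.ones((2, 2)), np.eye(2))


class TestFit:
    def test_same_seed_bit_identical(self, planted_noisy_small):
        X, P, _ = planted_noisy_small
        model = PDJDSNMF(X, P, dims=[6, 4])
        a = model.fit(max_iter=60, seed=3)
        b = model.fit(max_iter=60, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a.params.parameters(), b.params.parameters()))
        np.testing.assert_array_equal(a.objective_trace, b.objective_trace)
        assert a.recon_corr == b.recon_corr

    def test_objective_trace_monotone_after_burn_in(self, planted_noisy_small):
        X, P, _ = planted_noisy_small
        model = PDJDSNMF(X, P, dims=[6, 4])
        res = model.fit(max_iter=250, seed=0)
        tr = res.objective_trace
        assert np.all(tr[11:] <= tr[10:-1] * (1 + 1e-6))

    def test_intermediate_layers_inside_unit_interval(self, planted_noisy_small):
        X, P, _ = planted_noisy_small
        model = PDJDSNMF(X, P, dims=[6, 4, 3])
        res = model.fit(max_iter=80, seed=0)
        for i in range(3):
            for layer in _layers(res.params, i)[:-1]:
                assert layer.min() > 0.0 and layer.max() < 1.0

    def test_lbfgs_solver_reaches_lower_objective(self, planted_noisy_small):
        X, P, _ = planted_noisy_small
        model = PDJDSNMF(X, P, dims=[6, 4])
        adam = model.fit(max_iter=150, seed=0)
        lb = model.fit(max_iter=150, seed=0, method="lbfgs")
        assert lb.objective_trace[-1] <= adam.objective_trace[-1] * 1.05

    def test_strong_laplacian_penalty_shrinks_laplacian_term(self, planted_noisy_small):
        """A large lambda3 must leave a smaller graph-smoothness term at
        convergence than a lambda3 = 0 fit of the same data."""
        X, P, _ = planted_noisy_small
        base = PDJDSNMF(X, P, dims=[6, 4], penalties=PenaltyWeights(1e-4, 0.0, 0.0),
                        graphs=None, tau=0.5)
        from pdjdsnmf import build_feature_graph
        graphs = [build_feature_graph(x, tau=0.5) for x in base.X]
        free = PDJDSNMF(X, P, dims=[6, 4], penalties=PenaltyWeights(1e-4, 0.0, 0.0),
                        graphs=graphs).fit(max_iter=300, seed=0)
        constrained = PDJDSNMF(X, P, dims=[6, 4], penalties=PenaltyWeights(1e-4, 0.0, 1e3),
                               graphs=graphs).fit(max_iter=300, seed=0)
        assert constrained.term_trace[-1, 3] < free.term_trace[-1, 3]

    def test_small_feature_count_rejected(self, rng):
        X = [make_omics(rng, 8, p, n) for p, n in zip((6, 5, 2), ("a", "b", "c"))]
        with pytest.raises(ValueError, match="k0"):
            PDJDSNMF(X, None, dims=[4, 2], penalties=PenaltyWeights(0, 0, 0))

    def test_mismatched_samples_rejected(self, rng):
        X1 = make_omics(rng, 6, 5, "a")
        X2 = make_omics(rng, 6, 5, "b")
        X2.sample_ids = [f"t{i}" for i in range(6)]
        with pytest.raises(ValueError, match="sample ids"):
            PDJDSNMF([X1, X2], None, dims=[2], penalties=PenaltyWeights(0, 0, 0))


class TestCheckpoint:
    def test_save_writes_matrices_and_manifest(self, tmp_path, planted_noisy_small):
        import json

        X, P, _ = planted_noisy_small
        model = PDJDSNMF(X, P, dims=[6, 4])
        res = model.fit(max_iter=30, seed=0)
        res.save(tmp_path / "ckpt")
        manifest = json.loads((tmp_path / "ckpt" / "manifest.json").read_text())
        assert manifest["dims"] == [6, 4]
        assert manifest["seed"] == 0
        for name in ("U.tsv", "H0_mrna.tsv", "Hdeep_lncrna.tsv", "Z_mirna_1.tsv"):
            assert (tmp_path / "ckpt" / name).exists()

    def test_summary_mentions_fit_facts(self, planted_noisy_small):
        X, P, _ = planted_noisy_small
        res = PDJDSNMF(X, P, dims=[6, 4]).fit(max_iter=20, seed=0)
        text = res.summary()
        assert "reconstruction Pearson correlation" in text
        assert "mrna" in text and "seed: 0" in text
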