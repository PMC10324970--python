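import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semgkit.lmd_lssvm import (DimScaler, FCMEncoder, HybridKernel,
                               LSSVMClassifier, fcm_encode, fuzzy_cmeans,
                               hybrid_gram, hybrid_kernel, lmd_decompose,
                               lmd_features, lssvm_fit, tune_lssvm)
from semgkit.dbn_elm import PSOConfig
from semgkit.trials import Trial


class TestLMD:
    def test_reconstruction_identity_any_input(self, rng):
        for _ in range(5):
            x = rng.standard_normal(500)
            pfs, resid = lmd_decompose(x, max_pf=4)
            recon = sum((p.pf for p in pfs), np.zeros_like(x)) + resid
            assert np.max(np.abs(recon - x)) < 1e-10

    def test_product_structure_of_components(self, rng):
        x = rng.standard_normal(400)
        pfs, _ = lmd_decompose(x, max_pf=3)
        for p in pfs:
            np.testing.assert_allclose(p.pf, p.envelope * p.fm, atol=1e-10)
            assert p.envelope.min() >= 0
            assert -1 - 1e-12 <= p.fm.min() and p.fm.max() <= 1 + 1e-12

    def test_am_envelope_recovered(self):
        fs = 1000
        t = np.arange(1000) / fs
        env_true = 1 + 0.5 * np.cos(2 * np.pi * 5 * t)
        x = env_true * np.cos(2 * np.pi * 80 * t)
        pfs, _ = lmd_decompose(x)
        k = 50  # trim 5 % edges
        r = np.corrcoef(pfs[0].envelope[k:-k], env_true[k:-k])[0, 1]
        assert r > 0.95

    def test_monotone_input_yields_no_product_functions(self):
        x = np.linspace(0, 1, 100) ** 2
        pfs, resid = lmd_decompose(x)
        assert len(pfs) == 0
        np.testing.assert_array_equal(resid, x)

    def test_tone_instantaneous_frequency(self):
        fs = 1000
        t = np.arange(1000) / fs
        trial = Trial(samples=np.cos(2 * np.pi * 80 * t)[:, None], fs=fs,
                      label=0)
        v = lmd_features(trial, n_pf=2)
        assert v[3] == pytest.approx(80.0, abs=1.0)  # mean IF of first PF

    def test_feature_length_and_zero_signal(self):
        trial = Trial(samples=np.zeros((200, 3)), fs=1000, label=0)
        v = lmd_features(trial, n_pf=4)
        assert v.shape == (3 * 4 * 5,)
        np.testing.assert_array_equal(v, 0.0)


class TestFuzzyCMeans:
    def test_separated_blobs_exact_recovery(self, rng):
        X = np.vstack([rng.standard_normal((50, 2)),
                       rng.standard_normal((50, 2)) + 20.0])
        labels = np.array([0] * 50 + [1] * 50)
        res = fuzzy_cmeans(X, 2, seed=0)
        hard = res.memberships.argmax(axis=1)
        acc = max(np.mean(hard == labels), np.mean(hard != labels))
        assert acc == 1.0
        means = np.array([X[:50].mean(0), X[50:].mean(0)])
        d = min(np.abs(res.centers - means).max(),
                np.abs(res.centers[::-1] - means).max())
        assert d < 0.1

    def test_memberships_row_stochastic(self, rng):
        X = rng.standard_normal((40, 3))
        res = fuzzy_cmeans(X, 3, seed=1)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0,
                                   atol=1e-12)
        assert res.memberships.min() >= 0

    def test_objective_nonincreasing_random_datasets(self, rng):
        for rep in range(20):
            X = rng.standard_normal((30, 4))
            res = fuzzy_cmeans(X, 3, seed=rep)
            assert np.all(np.diff(res.objective) <= 1e-9)

    def test_coincident_point_gets_crisp_membership(self, rng):
        X = rng.standard_normal((20, 2))
        res = fuzzy_cmeans(X, 2, seed=0)
        U = fcm_encode(res.centers[:1], res, mode="memberships")
        assert U[0].max() == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            fuzzy_cmeans(X, 1)
        with pytest.raises(ValueError):
            fuzzy_cmeans(X, 2, m_exp=1.0)
        with pytest.raises(ValueError):
            fuzzy_cmeans(X, 11)


class TestFCMEncode:
    def test_concat_width(self, rng):
        X = rng.standard_normal((30, 4))
        res = fuzzy_cmeans(X, 3, seed=0)
        out = fcm_encode(X, res, mode="concat")
        assert out.shape == (30, 7)
        out2 = fcm_encode(X, res, mode="memberships")
        assert out2.shape == (30, 3)

    def test_deterministic_given_centers(self, rng):
        X = rng.standard_normal((30, 4))
        res = fuzzy_cmeans(X, 3, seed=0)
        np.testing.assert_array_equal(fcm_encode(X, res), fcm_encode(X, res))

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((30, 4))
        res = fuzzy_cmeans(X, 3, seed=0)
        with pytest.raises(ValueError):
            fcm_encode(rng.standard_normal((5, 3)), res)

    def test_sklearn_encoder_pipeline_contract(self, rng):
        X = rng.standard_normal((30, 4))
        enc = FCMEncoder(n_clusters=3, random_state=0).fit(X)
        out = enc.transform(X)
        assert out.shape == (30, 7)


class TestHybridKernel:
    def test_pure_rbf_diagonal_is_one(self, rng):
        k = HybridKernel(a=1.0, sigma2=2.0, order=3)
        p = rng.standard_normal(4)
        assert hybrid_kernel(p, p, k) == pytest.approx(1.0)

    def test_pure_polynomial_hand_case(self):
        k = HybridKernel(a=0.0, sigma2=1.0, order=1)
        assert hybrid_kernel(np.ones(2), np.ones(2), k) == pytest.approx(3.0)

    def test_matches_scalar_evaluation_on_random_pairs(self, rng):
        k = HybridKernel(a=0.5, sigma2=1.7, order=2)
        for _ in range(100):
            p, q = rng.standard_normal((2, 5))
            direct = (0.5 * np.exp(-np.sum((p - q) ** 2) / (2 * 1.7))
                      + 0.5 * (p @ q + 1.0) ** 2)
            assert hybrid_kernel(p, q, k) == pytest.approx(direct, rel=1e-12)

    def test_mix_limits_equal_pure_kernels(self, rng):
        P = rng.standard_normal((10, 3))
        rbf_only = hybrid_gram(P, P, HybridKernel(a=1.0, sigma2=1.0, order=2))
        poly_only = hybrid_gram(P, P, HybridKernel(a=0.0, sigma2=1.0, order=2))
        half = hybrid_gram(P, P, HybridKernel(a=0.5, sigma2=1.0, order=2))
        np.testing.assert_allclose(half, 0.5 * rbf_only + 0.5 * poly_only,
                                   rtol=1e-12)

    @given(st.floats(0, 1), st.floats(0.1, 10), st.integers(1, 4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_gram_matrices_positive_semidefinite(self, a, sigma2, order):
        rng = np.random.default_rng(7)
        P = rng.standard_normal((12, 3))
        G = hybrid_gram(P, P, HybridKernel(a=a, sigma2=sigma2, order=order))
        evals = np.linalg.eigvalsh(0.5 * (G + G.T))
        assert evals.min() >= -1e-8 * np.trace(G)

    def test_invalid_mix_weight_rejected(self):
        with pytest.raises(ValueError):
            HybridKernel(a=1.5)


class TestLSSVM:
    def test_kkt_residual_small_on_random_problems(self, rng):
        for rep in range(5):
            X = rng.standard_normal((40, 3))
            y = np.sign(rng.standard_normal(40))
            y[y == 0] = 1
            model = LSSVMClassifier(kernel="rbf", sigma2=1.0,
                                    gamma_reg=10.0).fit(X, y)
            assert model.machines_[(0, 1)].kkt_residual_ < 1e-8

    def test_xor_solved_with_rbf(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]])
        y = np.array([0, 1, 1, 0])
        model = LSSVMClassifier(kernel="rbf", sigma2=0.5,
                                gamma_reg=100.0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_vanishing_gamma_predicts_majority(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.array([0] * 20 + [1] * 10)
        model = LSSVMClassifier(kernel="rbf", sigma2=1.0,
                                gamma_reg=1e-8).fit(X, y)
        machine = model.machines_[(0, 1)]
        assert np.abs(machine.alpha_).max() < 1e-6
        assert np.all(model.predict(rng.standard_normal((20, 2))) == 0)

    def test_three_separated_gaussians_fit_perfectly(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)) + off
                       for off in ((0, 0), (8, 0), (0, 8))])
        y = np.repeat([0, 1, 2], 20)
        model = lssvm_fit(X, y, gamma_reg=100.0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_two_class_multiclass_equals_binary_machine(self, rng):
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(int)
        model = LSSVMClassifier(kernel="rbf", sigma2=1.0,
                                gamma_reg=10.0).fit(X, y)
        machine = model.machines_[(0, 1)]
        d = machine.decision(X)
        expected = np.where(d > 0, 0, 1)
        np.testing.assert_array_equal(model.predict(X), expected)

    def test_label_permutation_permutes_predictions(self, rng):
        X = np.vstack([rng.standard_normal((15, 2)) + off
                       for off in ((0, 0), (6, 0), (0, 6))])
        y = np.repeat([0, 1, 2], 15)
        perm = {0: 2, 1: 0, 2: 1}
        y_perm = np.array([perm[v] for v in y])
        a = LSSVMClassifier(kernel="rbf", gamma_reg=50.0).fit(X, y)
        b = LSSVMClassifier(kernel="rbf", gamma_reg=50.0).fit(X, y_perm)
        np.testing.assert_array_equal(
            np.array([perm[v] for v in a.predict(X)]), b.predict(X))

    def test_dim_scaler_normalizes_inner_products(self, rng):
        X = rng.standard_normal((20, 100))
        Z = DimScaler().fit_transform(X)
        assert np.mean(np.sum(Z**2, axis=1)) == pytest.approx(1.0, rel=0.3)


class TestTuneLSSVM:
    def test_collapsed_bounds_return_that_point(self, rng):
        X = np.vstack([rng.standard_normal((15, 2)),
                       rng.standard_normal((15, 2)) + 4.0])
        y = np.repeat([0, 1], 15)
        bounds = {"a": (0.4, 0.4), "log_sigma2": (0.0, 0.0),
                  "log_gamma": (2.0, 2.0), "order": (2.0, 2.0)}
        model, params = tune_lssvm(
            X, y, cfg=PSOConfig(swarm_size=3, iterations=2, seed=0),
            bounds=bounds, folds=3)
        assert params["mix_weight"] == pytest.approx(0.4)
        assert params["degree"] == 2
        assert params["sigma2"] == pytest.approx(1.0)

    def test_tuned_no_worse_than_random_draws(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)),
                       rng.standard_normal((20, 2)) + 2.0])
        y = np.repeat([0, 1], 20)
        model, params = tune_lssvm(
            X, y, cfg=PSOConfig(swarm_size=5, iterations=5, seed=0), folds=3)
        from sklearn.model_selection import cross_val_score
        tuned = cross_val_score(
            LSSVMClassifier(kernel="hybrid", **params), X, y, cv=3).mean()
        randoms = []
        for s in range(10):
            r = np.random.default_rng(s)
            clf = LSSVMClassifier(kernel="hybrid",
                                  mix_weight=r.random(),
                                  sigma2=float(np.exp(r.uniform(-3, 5))),
                                  gamma_reg=float(np.exp(r.uniform(-2, 5))),
                                  degree=int(r.integers(1, 5)))
            randoms.append(cross_val_score(clf, X, y, cv=3).mean())
        assert tuned >= np.median(randoms) - 1e-9
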