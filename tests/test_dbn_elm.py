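import itertools

import numpy as np
import pytest

from semgkit.dbn_elm import (RBM, BBNELMClassifier, PSOConfig, elm_solve,
                             fit_bbn_elm, pretrain_bbn, pso_minimize,
                             pso_topology_search, rbm_cd1_step, _sigmoid)


def exact_loglik_gradient(rbm: RBM, data: np.ndarray):
    """Exact log-likelihood gradient of a tiny RBM by enumerating all
    joint (v, h) states; the independent oracle for the CD-1 check."""
    nv, nh = rbm.n_visible, rbm.n_hidden
    vs = np.array(list(itertools.product([0, 1], repeat=nv)), dtype=float)
    hs = np.array(list(itertools.product([0, 1], repeat=nh)), dtype=float)
    energy = vs @ rbm.w @ hs.T + (vs @ rbm.b_vis)[:, None] + (hs @ rbm.b_hid)[None, :]
    P = np.exp(energy)
    P /= P.sum()
    Evh = np.zeros_like(rbm.w)
    Ev = np.zeros(nv)
    Eh = np.zeros(nh)
    for i, v in enumerate(vs):
        for j, h in enumerate(hs):
            Evh += P[i, j] * np.outer(v, h)
            Ev += P[i, j] * v
            Eh += P[i, j] * h
    ph = _sigmoid(rbm.b_hid + data @ rbm.w)
    return (data.T @ ph / len(data) - Evh,
            data.mean(axis=0) - Ev, ph.mean(axis=0) - Eh)


class TestRBM:
    def test_zero_parameters_give_half_probabilities(self):
        rbm = RBM(w=np.zeros((4, 3)), b_vis=np.zeros(4), b_hid=np.zeros(3))
        v = np.array([[1.0, 0.0, 1.0, 1.0]])
        np.testing.assert_allclose(rbm.hidden_probs(v), 0.5)

    def test_batch_outside_unit_interval_rejected(self):
        rbm = RBM.initialize(3, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            rbm_cd1_step(rbm, np.array([[1.5, 0.0, 0.0]]),
                         np.random.default_rng(0))

    def test_cd1_learns_repeated_pattern(self):
        pattern = np.tile([1.0, 0, 1, 1, 0, 0], (16, 1))
        rbm = RBM.initialize(6, 4, np.random.default_rng(0), lr=0.2)
        rng = np.random.default_rng(1)
        for _ in range(500):
            rbm = rbm_cd1_step(rbm, pattern, rng)
        ph = rbm.hidden_probs(pattern)
        h = (rng.random(ph.shape) < ph).astype(float)
        recon = rbm.visible_probs(h)
        assert np.abs(recon - pattern).mean() < 0.05

    def test_cd1_aligns_with_exact_gradient(self):
        """CD-1 update direction vs brute-force log-likelihood gradient
        (3 visible x 2 hidden; all 2^5 states enumerated)."""
        rng = np.random.default_rng(0)
        hits = 0
        for trial in range(100):
            rbm = RBM(w=rng.normal(0, 0.5, (3, 2)),
                      b_vis=rng.normal(0, 0.5, 3),
                      b_hid=rng.normal(0, 0.5, 2), lr=0.1)
            data = (rng.random((100, 3)) < rng.random(3)).astype(float)
            new = rbm_cd1_step(rbm, data, np.random.default_rng(trial))
            gw, gv, gh = exact_loglik_gradient(rbm, data)
            inner = (np.sum((new.w - rbm.w) * gw)
                     + np.sum((new.b_vis - rbm.b_vis) * gv)
                     + np.sum((new.b_hid - rbm.b_hid) * gh))
            hits += inner > 0
        assert hits >= 90

    def test_update_vanishes_when_data_matches_model(self):
        """When the training distribution equals the model distribution the
        expected CD-1 update shrinks with sample size."""
        rng = np.random.default_rng(2)
        rbm = RBM(w=rng.normal(0, 0.3, (3, 2)), b_vis=rng.normal(0, 0.3, 3),
                  b_hid=rng.normal(0, 0.3, 2), lr=1.0)
        vs = np.array(list(itertools.product([0, 1], repeat=3)), dtype=float)
        hs = np.array(list(itertools.product([0, 1], repeat=2)), dtype=float)
        energy = vs @ rbm.w @ hs.T + (vs @ rbm.b_vis)[:, None] + (hs @ rbm.b_hid)[None, :]
        pv = np.exp(energy).sum(axis=1)
        pv /= pv.sum()
        norms = []
        for n in (200, 2000, 20000):
            idx = rng.choice(len(vs), size=n, p=pv)
            new = rbm_cd1_step(rbm, vs[idx], np.random.default_rng(0))
            norms.append(np.linalg.norm(new.w - rbm.w))
        assert norms[-1] < norms[0]
        assert norms[-1] < 0.05


class TestPretrain:
    def test_zero_epochs_gives_seeded_random_stack(self, rng):
        X = rng.random((20, 6))
        a = pretrain_bbn(X, [6, 4, 3], epochs=0, seed=5)
        b = pretrain_bbn(X, [6, 4, 3], epochs=0, seed=5)
        assert len(a) == 2
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.w, rb.w)

    def test_topology_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pretrain_bbn(rng.random((10, 5)), [4, 3], epochs=1)

    def test_training_reduces_reconstruction_error(self, rng):
        # structured binary data: two prototype patterns plus flip noise
        protos = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1.0]])
        X = protos[rng.integers(0, 2, 200)]
        X = np.abs(X - (rng.random(X.shape) < 0.05))

        def recon_error(stack):
            ph = stack[0].hidden_probs(X)
            return np.abs(stack[0].visible_probs(ph) - X).mean()

        untrained = pretrain_bbn(X, [6, 4], epochs=0, seed=0)
        trained = pretrain_bbn(X, [6, 4], epochs=30, lr=0.2, seed=0)
        assert recon_error(trained) < recon_error(untrained)


class TestELM:
    def test_square_nonsingular_interpolates(self, rng):
        H = rng.standard_normal((10, 10))
        T = np.eye(10)[rng.integers(0, 3, 10)]
        beta = elm_solve(H, T)
        assert np.abs(H @ beta - T).max() < 1e-8

    def test_minimum_norm_among_solutions(self, rng):
        # rank-deficient H: any null-space perturbation grows the norm
        H = rng.standard_normal((8, 4)) @ rng.standard_normal((4, 6))
        T = rng.standard_normal((8, 2))
        beta = elm_solve(H, T)
        _, _, Vt = np.linalg.svd(H)
        null = Vt[4:].T   # columns spanning the null space of H
        for i in range(null.shape[1]):
            Z = np.outer(null[:, i], np.ones(2))
            assert np.linalg.norm(beta) <= np.linalg.norm(beta + 0.1 * Z) + 1e-12
            np.testing.assert_allclose(H @ (beta + Z), H @ beta, atol=1e-8)

    def test_equals_ridgeless_normal_equations(self, rng):
        H = rng.standard_normal((12, 5))
        T = rng.standard_normal((12, 3))
        beta = elm_solve(H, T)
        ridge = np.linalg.solve(H.T @ H + 1e-12 * np.eye(5), H.T @ T)
        np.testing.assert_allclose(beta, ridge, atol=1e-6)


class TestBBNELM:
    def _gaussian_classes(self, rng, n=200):
        X = np.vstack([rng.standard_normal((n // 2, 4)),
                       rng.standard_normal((n // 2, 4)) + 4.0])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_untrained_random_projection_still_separates(self, rng):
        X, y = self._gaussian_classes(rng)
        model = BBNELMClassifier(hidden_layers=(16,), epochs=0, bp_epochs=0,
                                 random_state=0).fit(X, y)
        assert np.mean(model.predict(X) == y) >= 0.8

    def test_perfect_fit_on_separable_three_class_toy(self, rng):
        X = np.vstack([rng.standard_normal((30, 3)) + off
                       for off in (0.0, 6.0, -6.0)])
        y = np.repeat([0, 1, 2], 30)
        model = fit_bbn_elm(X, y, topology=(16,), epochs=3, bp_epochs=10,
                            seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_deterministic_given_seed(self, rng):
        X, y = self._gaussian_classes(rng, n=60)
        a = fit_bbn_elm(X, y, topology=(8,), epochs=2, bp_epochs=5, seed=3)
        b = fit_bbn_elm(X, y, topology=(8,), epochs=2, bp_epochs=5, seed=3)
        np.testing.assert_array_equal(a.beta_, b.beta_)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            BBNELMClassifier().fit(X, np.zeros(10))

    def test_save_load_round_trip(self, rng, tmp_path):
        X, y = self._gaussian_classes(rng, n=60)
        model = fit_bbn_elm(X, y, topology=(8,), epochs=2, bp_epochs=0, seed=0)
        path = tmp_path / "model.npz"
        model.save(str(path))
        back = BBNELMClassifier.load(str(path))
        np.testing.assert_array_equal(model.predict(X), back.predict(X))


class TestPSO:
    def test_sphere_benchmark(self):
        best_x, best_f, _ = pso_minimize(
            lambda x: float(np.sum(x**2)), [(-5, 5)] * 5,
            PSOConfig(swarm_size=20, iterations=100, seed=0))
        assert best_f < 1e-3

    def test_swarm_at_optimum_stays(self):
        cfg = PSOConfig(swarm_size=4, iterations=10, seed=0)
        best_x, best_f, _ = pso_minimize(
            lambda x: float(np.sum(x**2)), [(-1, 1)] * 3, cfg,
            x0=np.zeros(3))
        assert best_f == 0.0

    def test_gbest_trace_monotone(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))

        def rosenbrock_ish(x):
            return float(np.sum((A @ x)**2) + np.sum(np.abs(x)))

        _, _, trace = pso_minimize(rosenbrock_ish, [(-3, 3)] * 4,
                                   PSOConfig(swarm_size=8, iterations=40,
                                             seed=1))
        assert np.all(np.diff(trace) <= 0)

    def test_nonfinite_objective_rejected_not_fatal(self):
        def holey(x):
            return np.nan if x[0] > 0 else float(x[0]**2)

        _, best_f, _ = pso_minimize(holey, [(-1, 1)],
                                    PSOConfig(swarm_size=6, iterations=20,
                                              seed=2))
        assert np.isfinite(best_f)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PSOConfig(swarm_size=1)
        with pytest.raises(ValueError):
            PSOConfig(iterations=0)


class TestTopologySearch:
    def _data(self, rng):
        X = np.vstack([rng.standard_normal((40, 4)) + off
                       for off in (0.0, 5.0)])
        y = np.repeat([0, 1], 40)
        return X, y

    def test_single_candidate_returned(self, rng):
        X, y = self._data(rng)
        model, topo, _ = pso_topology_search(
            X, y, candidate_widths=[12], depth_range=(1, 1),
            cfg=PSOConfig(swarm_size=3, iterations=2, seed=0), epochs=1,
            bp_epochs=0)
        assert topo == (12,)

    def test_prefers_reasonable_width_over_degenerate(self, rng):
        X, y = self._data(rng)
        picks = []
        for seed in range(5):
            _, topo, _ = pso_topology_search(
                X, y, candidate_widths=[1, 16], depth_range=(1, 1),
                cfg=PSOConfig(swarm_size=4, iterations=4, seed=seed),
                epochs=1, bp_epochs=0)
            picks.append(topo[0])
        assert sum(p == 16 for p in picks) >= 4

    def test_empty_candidate_set_rejected(self, rng):
        X, y = self._data(rng)
        with pytest.raises(ValueError):
            pso_topology_search(X, y, candidate_widths=[], depth_range=(1, 1))
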