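import numpy as np
import pytest

from eqprop import (
    Hyperparameters,
    LayerSpec,
    NetworkState,
    PersistentStore,
    RelaxationConfig,
    apply_updates,
    bias_corrections,
    build_mlff,
    draw_beta,
    fit,
    initialize_parameters,
    make_synthetic,
    relax,
    rewire_small_world,
    state_gradient,
    train_batch,
    weight_corrections,
)
from eqprop.training import CorrectionPair
from oracles import fd_cost_gradient


def _full_mask(n):
    m = ~np.eye(n, dtype=bool)
    return m


class TestCorrections:
    def test_identical_phases_give_zero(self):
        u = np.array([0.2, 0.5, 0.8])
        assert np.all(weight_corrections(u, u, 1.0, _full_mask(3)) == 0)
        assert np.all(bias_corrections(u, u, 1.0, 1) == 0)

    def test_weight_correction_direct_substitution(self):
        # rho products: 0.5 (clamped) vs 0.4 (free) -> dW = 0.1 at beta=1
        u0 = np.array([0.5, 0.8])
        ub = np.array([0.625, 0.8])
        dW = weight_corrections(u0, ub, 1.0, _full_mask(2))
        assert dW[0, 1] == pytest.approx(0.1)
        assert dW[1, 0] == pytest.approx(0.1)
        # the sign of the correction flips with the sign of beta
        dW_neg = weight_corrections(u0, ub, -1.0, _full_mask(2))
        assert dW_neg[0, 1] == pytest.approx(-0.1)

    def test_bias_correction_direct_substitution(self):
        u0 = np.array([0.1, 0.5])
        ub = np.array([0.9, 0.6])
        db = bias_corrections(u0, ub, 0.5, 1)
        assert db[1] == pytest.approx(0.2)
        assert db[0] == 0.0  # input neuron biases are untrainable

    def test_beta_zero_rejected(self):
        u = np.zeros(3)
        with pytest.raises(ValueError):
            weight_corrections(u, u, 0.0, _full_mask(3))
        with pytest.raises(ValueError):
            bias_corrections(u, u, 0.0, 1)

    def test_corrections_respect_mask_and_symmetry(self, small_net, rng):
        topo, _ = small_net
        u0 = rng.uniform(0, 1, (14, 5))
        ub = rng.uniform(0, 1, (14, 5))
        dW = weight_corrections(u0, ub, 0.7, topo.mask)
        assert np.array_equal(dW, dW.T)
        assert np.all(dW[~topo.mask] == 0)

    def test_locality_non_endpoint_state_is_irrelevant(self):
        # dW_ij depends only on the two endpoint activations
        rng = np.random.default_rng(0)
        u0 = rng.uniform(0, 1, 6)
        ub = rng.uniform(0, 1, 6)
        mask = _full_mask(6)
        before = weight_corrections(u0, ub, 1.0, mask)[1, 2]
        u0b, ubb = u0.copy(), ub.copy()
        u0b[4] = 0.123
        ubb[5] = 0.987
        after = weight_corrections(u0b, ubb, 1.0, mask)[1, 2]
        assert before == after


class TestApplyUpdates:
    def test_zero_rate_is_identity(self, small_net, rng):
        topo, params = small_net
        corr = CorrectionPair(
            weight_corrections(
                rng.uniform(0, 1, 14), rng.uniform(0, 1, 14), 1.0, topo.mask
            ),
            rng.normal(0, 1, 14),
        )
        hp = Hyperparameters(alpha=0.0, n_free=1, n_clamped=1)
        out = apply_updates(params, corr, hp, topo)
        assert np.array_equal(out.W, params.W)

    def test_global_rate_scales_both_triangles(self):
        topo = build_mlff((1, 1))
        params = initialize_parameters(topo, np.random.default_rng(0))
        dW = np.array([[0.0, 0.1], [0.1, 0.0]])
        corr = CorrectionPair(dW, np.zeros(2))
        hp = Hyperparameters(alpha=0.02, n_free=1, n_clamped=1)
        out = apply_updates(params, corr, hp, topo)
        assert out.W[0, 1] - params.W[0, 1] == pytest.approx(0.002)
        assert out.W[1, 0] - params.W[1, 0] == pytest.approx(0.002)

    def test_per_layer_rates_scale_their_groups(self):
        topo = build_mlff((2, 2, 2, 2))
        n = topo.layers.n
        params = initialize_parameters(topo, np.random.default_rng(0))
        dW = np.where(topo.mask, 1.0, 0.0)
        db = np.ones(n)
        rates = (0.128, 0.032, 0.008)
        hp = Hyperparameters(alpha=rates, n_free=1, n_clamped=1)
        out = apply_updates(params, CorrectionPair(dW, db), hp, topo)
        delta = out.W - params.W
        assert delta[0, 2] == pytest.approx(0.128)  # layers 1-2
        assert delta[2, 4] == pytest.approx(0.032)  # layers 2-3
        assert delta[4, 6] == pytest.approx(0.008)  # layers 3-4
        db_applied = out.b - params.b
        assert np.allclose(db_applied[:2], 0)  # input biases never train
        assert np.allclose(db_applied[2:4], 0.128)
        assert np.allclose(db_applied[6:], 0.008)  # output biases use alpha_{N+1}

    def test_per_layer_rejected_with_skips(self):
        sw = rewire_small_world(
            build_mlff((2, 2, 2, 2)), 1.0, np.random.default_rng(0)
        )
        params = initialize_parameters(sw, np.random.default_rng(0))
        corr = CorrectionPair(np.zeros_like(params.W), np.zeros_like(params.b))
        hp = Hyperparameters(alpha=(0.1, 0.1, 0.1), n_free=1, n_clamped=1)
        with pytest.raises(ValueError):
            apply_updates(params, corr, hp, sw)

    def test_wrong_rate_count_rejected(self, small_net):
        topo, params = small_net
        corr = CorrectionPair(np.zeros_like(params.W), np.zeros_like(params.b))
        hp = Hyperparameters(alpha=(0.1, 0.1), n_free=1, n_clamped=1)
        with pytest.raises(ValueError):
            apply_updates(params, corr, hp, topo)


class TestDrawBeta:
    def test_magnitude_and_randomized_sign(self):
        hp = Hyperparameters(beta_magnitude=0.8, n_free=1, n_clamped=1)
        rng = np.random.default_rng(0)
        draws = np.array([draw_beta(hp, rng) for _ in range(10_000)])
        assert np.all(np.abs(draws) == 0.8)
        # empirical mean within 3 sigma of 0
        sigma = 0.8 / np.sqrt(len(draws))
        assert abs(draws.mean()) < 3 * sigma

    def test_fixed_seed_reproducible(self):
        hp = Hyperparameters(n_free=1, n_clamped=1)
        a = [draw_beta(hp, np.random.default_rng(7)) for _ in range(5)]
        b = [draw_beta(hp, np.random.default_rng(7)) for _ in range(5)]
        assert a == b

    def test_sign_randomization_off(self):
        hp = Hyperparameters(
            beta_magnitude=0.5, randomize_beta_sign=False, n_free=1, n_clamped=1
        )
        rng = np.random.default_rng(0)
        assert all(draw_beta(hp, rng) == 0.5 for _ in range(20))


class TestTrainBatch:
    def _setup(self, seed=0):
        topo = build_mlff((3, 5, 4, 2))
        rng = np.random.default_rng(seed)
        params = initialize_parameters(topo, rng)
        X = rng.uniform(0.1, 0.9, (6, 3))
        Y = np.eye(2)[rng.integers(0, 2, 6)]
        return topo, params, X, Y

    def test_zero_rate_keeps_parameters(self):
        topo, params, X, Y = self._setup()
        hp = Hyperparameters(alpha=0.0, n_free=100, n_clamped=8)
        res = train_batch(
            params, topo, X, Y, PersistentStore(), hp, np.random.default_rng(0)
        )
        assert np.array_equal(res.params.W, params.W)
        assert res.predictions.shape == (6, 2)
        assert 0.0 <= res.error <= 1.0

    def test_equilibrium_target_gives_zero_corrections(self):
        # when the target equals the free-phase output the clamped phase
        # stays at the free equilibrium and every correction vanishes
        topo, params, X, _ = self._setup()
        hp = Hyperparameters(alpha=0.1, n_free=4000, n_clamped=50,
                             randomize_beta_sign=False)
        free = relax(
            NetworkState.cold_start(topo.layers, X.T),
            params,
            RelaxationConfig(hp.eps, hp.n_free, 0.0),
        )
        res = train_batch(
            params, topo, X, free.y.T.copy(), PersistentStore(), hp,
            np.random.default_rng(0),
        )
        assert np.max(np.abs(res.corrections.dW)) < 1e-6
        assert np.max(np.abs(res.corrections.db)) < 1e-6

    def test_empty_batch_rejected(self):
        topo, params, X, Y = self._setup()
        hp = Hyperparameters(n_free=2, n_clamped=2)
        with pytest.raises(ValueError):
            train_batch(
                params, topo, X[:0], Y[:0], PersistentStore(), hp,
                np.random.default_rng(0),
            )

    def test_symmetry_and_mask_preserved_over_many_updates(self):
        topo, params, X, Y = self._setup()
        hp = Hyperparameters(alpha=0.5, n_free=30, n_clamped=5)
        store = PersistentStore()
        rng = np.random.default_rng(1)
        for _ in range(20):
            res = train_batch(params, topo, X, Y, store, hp, rng)
            params = res.params
        assert np.array_equal(params.W, params.W.T)
        assert np.all(params.W[~topo.mask] == 0)
        assert not params.W.diagonal().any()

    def test_gradient_theorem_on_batch(self):
        # batch-averaged -dW aligns with the finite-difference gradient of
        # the free-fixed-point cost (the core correctness oracle)
        topo, params, X, Y = self._setup(seed=3)
        hp = Hyperparameters(
            alpha=0.0, beta_magnitude=0.005, n_free=2000, n_clamped=2000,
            randomize_beta_sign=False,
        )
        res = train_batch(
            params, topo, X, Y, PersistentStore(), hp, np.random.default_rng(0)
        )
        ii, jj = topo.edge_index
        minus_dw = -res.corrections.dW[ii, jj]
        g = fd_cost_gradient(params, topo, X, Y, n_iter=2000)
        cosine = np.dot(minus_dw, g) / (np.linalg.norm(minus_dw) * np.linalg.norm(g))
        assert cosine >= 0.95

    def test_beta_sign_average_reduces_bias(self):
        # the +/-beta average is closer to the small-beta gradient than
        # either sign alone (second-order error cancellation)
        topo, params, X, Y = self._setup(seed=5)
        g = fd_cost_gradient(params, topo, X, Y, n_iter=3000)
        ii, jj = topo.edge_index
        free = relax(
            NetworkState.cold_start(topo.layers, X.T), params,
            RelaxationConfig(0.5, 3000, 0.0),
        )
        est = {}
        for beta in (0.05, -0.05):
            clamped = relax(
                free, params, RelaxationConfig(0.5, 3000, beta), y_d=Y.T
            )
            dw = weight_corrections(free.u, clamped.u, beta, topo.mask)
            est[beta] = -dw[ii, jj]
        avg = (est[0.05] + est[-0.05]) / 2
        d_avg = np.linalg.norm(avg - g)
        assert d_avg <= np.linalg.norm(est[0.05] - g)
        assert d_avg <= np.linalg.norm(est[-0.05] - g)


class TestFitAndPersistence:
    def test_fit_log_shapes_and_zero_rate(self):
        ds = make_synthetic(2, 4, 20, seed=0)
        topo = build_mlff((4, 6, 2))
        params = initialize_parameters(topo, np.random.default_rng(0))
        hp = Hyperparameters(alpha=0.0, n_free=50, n_clamped=5, epochs=1)
        log = fit(params, topo, ds, hp, np.random.default_rng(0))
        assert len(log.epoch_log) == 1
        assert {"epoch", "batch", "beta", "error"} <= set(log.batch_log.columns)
        assert np.array_equal(log.params.W, params.W)  # alpha = 0

    def test_fit_deterministic(self):
        ds = make_synthetic(2, 4, 20, seed=0)
        topo = build_mlff((4, 6, 2))
        params = initialize_parameters(topo, np.random.default_rng(0))
        hp = Hyperparameters(alpha=0.05, n_free=40, n_clamped=5, epochs=2)
        a = fit(params, topo, ds, hp, np.random.default_rng(9))
        b = fit(params, topo, ds, hp, np.random.default_rng(9))
        assert a.batch_log.to_csv() == b.batch_log.to_csv()
        assert a.epoch_log.to_csv() == b.epoch_log.to_csv()

    def test_empty_dataset_rejected(self):
        ds = make_synthetic(2, 4, 20, seed=0)
        ds.X_train = ds.X_train[:0]
        ds.Y_train = ds.Y_train[:0]
        topo = build_mlff((4, 6, 2))
        params = initialize_parameters(topo, np.random.default_rng(0))
        hp = Hyperparameters(n_free=2, n_clamped=2)
        with pytest.raises(ValueError):
            fit(params, topo, ds, hp, np.random.default_rng(0))

    def test_persistent_particles_reduce_startup_gradient(self):
        # with frozen parameters, starting epoch 2 from the cached
        # equilibria leaves (at most) the epoch-1 startup gradient
        ds = make_synthetic(2, 4, 20, seed=1)
        topo = build_mlff((4, 6, 2))
        params = initialize_parameters(topo, np.random.default_rng(0))
        hp = Hyperparameters(alpha=0.0, n_free=500, n_clamped=5, batch_size=10)
        store = PersistentStore()
        norms = {1: [], 2: []}
        for epoch in (1, 2):
            for bi in range(0, ds.n_train, hp.batch_size):
                batch_id = bi // hp.batch_size
                X = ds.X_train[bi : bi + hp.batch_size]
                u = store.get(batch_id)
                if u is None:
                    state = NetworkState.cold_start(topo.layers, X.T)
                else:
                    u = u.copy()
                    u[: topo.layers.n_input] = X.T
                    state = NetworkState(topo.layers, u)
                g = state_gradient(state, params)
                norms[epoch].append(float(np.max(np.abs(g))))
                train_batch(
                    params, topo, X, ds.Y_train[bi : bi + hp.batch_size],
                    store, hp, np.random.default_rng(0), batch_id=batch_id,
                )
        assert all(n2 <= n1 for n1, n2 in zip(norms[1], norms[2]))

    def test_store_round_trip(self, tmp_path):
        store = PersistentStore()
        store.put(0, np.arange(6.0))
        store.put(3, np.ones((4, 2)))
        path = tmp_path / "store.npz"
        store.save(path)
        loaded = PersistentStore.load(path)
        assert np.array_equal(loaded.get(0), np.arange(6.0))
        assert np.array_equal(loaded.get(3), np.ones((4, 2)))
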