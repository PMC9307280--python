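"""Surrogate network: architecture, parameter counting, scaling,
prediction, metrics, training and grid search."""

import time

import numpy as np
import pytest

from willisflow.surrogate import (Hyperparameters, build_model,
                                  count_parameters, fit_scaling,
                                  evaluate_metrics, mse_loss, r2_score,
                                  mae_per_output, train, grid_search,
                                  SurrogateModel)


class TestArchitecture:
    def test_best_combination_shape_chain(self):
        m = build_model(Hyperparameters(7, 200, 3000, 10 ** -2.5), 60, 45)
        shapes = [w.shape for w in m.W]
        assert shapes[0] == (200, 60)
        assert shapes[1:-1] == [(200, 200)] * 6
        assert shapes[-1] == (45, 200)

    def test_same_seed_identical_initial_weights(self):
        hp = Hyperparameters(3, 16, 10, 1e-3)
        a = build_model(hp, 5, 4, seed=42)
        b = build_model(hp, 5, 4, seed=42)
        for wa, wb in zip(a.W, b.W):
            assert np.array_equal(wa, wb)

    def test_smallest_network_shapes(self):
        m = build_model(Hyperparameters(1, 1, 10, 1e-3), 60, 45)
        assert m.W[0].shape == (1, 60)
        assert m.W[1].shape == (45, 1)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_model(Hyperparameters(1, 1, 10, 1e-3), 0, 4)


class TestParameterCount:
    def test_reference_architecture_count(self):
        m = build_model(Hyperparameters(7, 200, 3000, 10 ** -2.5), 60, 45)
        assert count_parameters(m) == 262_445

    def test_minimal_network_count(self):
        # 1 hidden node: (60*1 + 1) + (1*45 + 45) = 151
        m = build_model(Hyperparameters(1, 1, 10, 1e-3), 60, 45)
        assert count_parameters(m) == 151

    @pytest.mark.parametrize("layers,nodes", [(2, 8), (3, 16), (5, 50)])
    def test_count_matches_brute_force_enumeration(self, layers, nodes):
        m = build_model(Hyperparameters(layers, nodes, 10, 1e-3), 7, 3)
        brute = sum(int(np.prod(w.shape)) for w in m.W) + \
            sum(b.size for b in m.b)
        assert count_parameters(m) == brute

    def test_node_doubling_grows_quadratically(self):
        def closed_form(nl, nn, din, dout):
            dims = [din] + [nn] * nl + [dout]
            return sum(dims[i + 1] * dims[i] + dims[i + 1]
                       for i in range(len(dims) - 1))
        for nn in (50, 100, 200):
            m = build_model(Hyperparameters(4, nn, 10, 1e-3), 60, 45)
            assert count_parameters(m) == closed_form(4, nn, 60, 45)


class TestScaling:
    def test_bounds_map_to_plus_minus_one(self):
        lo = np.array([0.0, -5.0])
        hi = np.array([2.0, 5.0])
        spec = fit_scaling(np.array([[1.0, 0.0]]), np.array([[1.0], [2.0]]),
                           lo, hi)
        assert np.allclose(spec.apply_x(lo[None, :]), -1.0)
        assert np.allclose(spec.apply_x(hi[None, :]), 1.0)

    def test_training_outputs_standardized(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(3.0, 2.5, size=(500, 4))
        spec = fit_scaling(rng.uniform(size=(500, 2)), Y)
        Ys = spec.apply_y(Y)
        assert np.all(np.abs(Ys.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(Ys.std(axis=0) - 1.0) < 1e-10)

    def test_validation_scaled_with_training_statistics(self):
        rng = np.random.default_rng(1)
        Y_train = rng.normal(0.0, 1.0, size=(200, 2))
        Y_val = rng.normal(10.0, 3.0, size=(50, 2))
        spec = fit_scaling(rng.uniform(size=(200, 2)), Y_train)
        Ys = spec.apply_y(Y_val)
        # scaled with mu_train/sigma_train, so the shift survives
        assert np.all(Ys.mean(axis=0) > 5.0)

    def test_invert_apply_round_trip(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(100, 3)) * 7 + 2
        spec = fit_scaling(rng.uniform(size=(100, 2)), Y)
        assert np.allclose(spec.invert_y(spec.apply_y(Y)), Y, atol=1e-12)

    def test_zero_variance_output_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling(np.random.uniform(size=(10, 2)),
                        np.ones((10, 2)))


class TestPredict:
    def _scaled_model(self, hp, d_in, d_out, seed=0):
        m = build_model(hp, d_in, d_out, seed)
        m.scaling = fit_scaling(np.random.default_rng(0).uniform(
            -1, 1, (50, d_in)), np.random.default_rng(1).normal(
            2.0, 1.0, (50, d_out)))
        return m

    def test_zero_weights_predict_training_mean(self):
        m = self._scaled_model(Hyperparameters(2, 8, 10, 1e-3), 3, 2)
        for w in m.W:
            w[:] = 0.0
        y = m.predict(np.zeros(3))
        assert np.allclose(y[0], m.scaling.y_mean, atol=1e-12)

    def test_hand_computed_forward_pass(self):
        """2-2-1 network with identity-like batch norm checked against
        pencil-and-paper matrix arithmetic."""
        m = build_model(Hyperparameters(1, 2, 10, 1e-3), 2, 1)
        m.W[0] = np.array([[1.0, 2.0], [-1.0, 0.5]])
        m.b[0] = np.array([0.1, -0.2])
        m.W[1] = np.array([[3.0, -1.0]])
        m.b[1] = np.array([0.5])
        x = np.array([[0.4, -0.3]])
        z = x @ m.W[0].T + m.b[0]            # [-0.1, -0.75]
        h = np.maximum(z / np.sqrt(1 + 1e-5), 0.0)   # eval-mode BN, ReLU
        expected = h @ m.W[1].T + m.b[1]
        out = m._forward(x)
        assert np.allclose(out, expected, atol=1e-12)
        assert expected[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_batched_equals_single_row_predictions(self):
        m = self._scaled_model(Hyperparameters(3, 16, 10, 1e-3), 4, 3, seed=5)
        X = np.random.default_rng(3).uniform(-1, 1, (20, 4))
        batch = m.predict(X)
        singles = np.vstack([m.predict(x) for x in X])
        assert np.allclose(batch, singles, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        m = self._scaled_model(Hyperparameters(1, 4, 10, 1e-3), 4, 2)
        with pytest.raises(ValueError):
            m.predict(np.zeros(7))

    def test_batched_prediction_latency(self):
        m = self._scaled_model(Hyperparameters(7, 200, 3000, 10 ** -2.5),
                               60, 45)
        X = np.random.default_rng(4).uniform(-1, 1, (10_000, 60))
        m.predict(X[:10])   # warm up
        t0 = time.time()
        m.predict(X)
        # order-of-magnitude bound only; wall time varies with the machine
        assert time.time() - t0 < 5.0


class TestMetrics:
    def test_perfect_prediction(self):
        Y = np.random.default_rng(0).normal(size=(30, 4))
        m = evaluate_metrics(Y, Y)
        assert m["mse_loss"] == 0.0
        assert m["r2"] == 1.0
        assert np.all(m["mae"] == 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        Y = np.random.default_rng(1).normal(size=(50, 3))
        pred = np.tile(Y.mean(axis=0), (50, 1))
        assert r2_score(Y, pred) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_half_r2(self):
        # refs {0, 2}, preds {0, 1}: SS_res = 1, SS_tot = 2
        assert r2_score(np.array([[0.0], [2.0]]),
                        np.array([[0.0], [1.0]])) == pytest.approx(0.5)

    def test_loss_is_mean_squared_error_per_sample_and_output(self):
        y = np.array([[1.0, 2.0], [3.0, 4.0]])
        p = np.array([[1.0, 0.0], [3.0, 1.0]])
        # sum of squares = 4 + 9 = 13; / (2 samples * 2 outputs)
        assert mse_loss(y, p) == pytest.approx(13.0 / 4.0)

    def test_mae_is_per_output(self):
        y = np.array([[0.0, 0.0], [2.0, 4.0]])
        p = np.array([[1.0, 0.0], [3.0, 0.0]])
        assert np.allclose(mae_per_output(y, p), [1.0, 2.0])

    def test_group_r2(self):
        Y = np.random.default_rng(2).normal(size=(40, 4))
        m = evaluate_metrics(Y, Y, groups={"flow": [0, 1], "pressure": [2, 3]})
        assert m["r2_flow"] == 1.0 and m["r2_pressure"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics(np.empty((0, 2)), np.empty((0, 2)))


class TestTraining:
    def _linear_problem(self, n=1500, d_in=5, d_out=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, (n, d_in))
        W = rng.normal(size=(d_out, d_in))
        Y = X @ W.T + 0.005 * rng.normal(size=(n, d_out))
        return X, Y

    def test_linear_target_is_learned(self):
        X, Y = self._linear_problem()
        m = build_model(Hyperparameters(2, 32, 200, 10 ** -2.5), 5, 3, seed=1)
        m, rep = train(m, X[:1000], Y[:1000], X[1000:1200], Y[1000:1200],
                       seed=1, max_epochs=600)
        assert rep.best_val_r2 > 0.99
        # oracle: least squares fit achieves the same data
        coef, *_ = np.linalg.lstsq(X[:1000], Y[:1000], rcond=None)
        r2_ls = r2_score(Y[1200:], X[1200:] @ coef)
        assert r2_score(Y[1200:], m.predict(X[1200:])) > r2_ls - 0.02

    def test_early_stopping_after_three_flat_windows(self):
        """Once the trailing-100-epoch validation R2 stops improving for
        three successive checks, training halts before max_epochs."""
        X, Y = self._linear_problem(n=400, d_in=3, d_out=2)
        m = build_model(Hyperparameters(1, 8, 100, 1e-2), 3, 2, seed=3)
        m, rep = train(m, X[:250], Y[:250], X[250:320], Y[250:320],
                       seed=3, max_epochs=5000)
        assert rep.stopping_epoch < 5000
        assert rep.stopping_epoch % 100 == 0
        assert rep.best_epoch <= rep.stopping_epoch

    def test_best_epoch_weights_are_restored(self):
        X, Y = self._linear_problem(n=600)
        m = build_model(Hyperparameters(2, 16, 100, 1e-2), 5, 3, seed=4)
        m, rep = train(m, X[:400], Y[:400], X[400:500], Y[400:500],
                       seed=4, max_epochs=400)
        # training-time validation R2 lives in scaled output space
        xs = m.scaling.apply_x(X[400:500])
        ys = m.scaling.apply_y(Y[400:500])
        r2_final = r2_score(ys, m._forward(xs))
        assert r2_final == pytest.approx(rep.best_val_r2, abs=1e-9)
        assert rep.best_val_r2 >= rep.val_r2_history[-1] - 1e-12

    def test_save_load_preserves_predictions(self, tmp_path):
        X, Y = self._linear_problem(n=300)
        m = build_model(Hyperparameters(2, 8, 50, 1e-2), 5, 3, seed=5)
        m, _ = train(m, X[:200], Y[:200], X[200:250], Y[200:250],
                     seed=5, max_epochs=100)
        m.save(tmp_path / "model.json")
        m2 = SurrogateModel.load(tmp_path / "model.json")
        assert np.allclose(m.predict(X[250:]), m2.predict(X[250:]),
                           atol=1e-12)


class TestGridSearch:
    def test_singleton_grid_returns_single_run(self):
        X, Y = TestTraining()._linear_problem(n=300)
        data = ((X[:200], Y[:200]), (X[200:250], Y[200:250]),
                (X[250:], Y[250:]))
        best, table = grid_search(
            {"n_hidden_layers": [1], "nodes_per_layer": [8],
             "batch_size": [50], "learning_rate": [1e-2]},
            *data, seed=0, max_epochs=100)
        assert len(table) == 1
        assert best is not None

    def test_selection_is_argmax_of_test_r2(self):
        X, Y = TestTraining()._linear_problem(n=400)
        data = ((X[:250], Y[:250]), (X[250:320], Y[250:320]),
                (X[320:], Y[320:]))
        best, table = grid_search(
            {"n_hidden_layers": [1, 2], "nodes_per_layer": [4, 16],
             "batch_size": [50], "learning_rate": [1e-2]},
            *data, seed=0, max_epochs=150)
        assert len(table) == 4
        best_row = table.loc[table.r2_test.idxmax()]
        assert r2_score(Y[320:], best.predict(X[320:])) == pytest.approx(
            best_row.r2_test, abs=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search({}, None, None, None)
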