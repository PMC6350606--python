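"""The sigmoid MLP: forward pass, error, updates, training loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cranioclass import (
    DataFormatError,
    DivergenceError,
    MeasurementDataset,
    NetworkConfig,
    NetworkState,
    backprop_update,
    compute_mse,
    evaluate,
    forward,
    init_state,
    load_model,
    network_outputs,
    predict,
    save_model,
    sigmoid,
    train_bpnn,
)
from cranioclass.data import one_hot
from cranioclass.synthetic import default_spec, generate


def random_state(shape=(6, 4, 2), seed=0, scale=0.5):
    M, Q, L = shape
    rng = np.random.default_rng(seed)
    return NetworkState(
        w_ih=rng.uniform(-scale, scale, (M, Q)),
        w_ho=rng.uniform(-scale, scale, (Q, L)),
        prev_delta_ih=np.zeros((M, Q)),
        prev_delta_ho=np.zeros((Q, L)),
    )


def objective(state, x, d, lam):
    """Per-sample regularized squared error 1/2 sum(d-y)^2 + lam/2 ||w||^2."""
    y = forward(state, x).output_out
    penalty = 0.5 * lam * (np.sum(state.w_ih**2) + np.sum(state.w_ho**2))
    return 0.5 * np.sum((d - y) ** 2) + penalty


def numeric_gradient(state, x, d, lam, h=1e-6):
    """Central finite differences of the objective in every weight."""
    grads = []
    for name in ("w_ih", "w_ho"):
        w = getattr(state, name)
        g = np.zeros_like(w)
        for idx in np.ndindex(w.shape):
            orig = w[idx]
            w[idx] = orig + h
            up = objective(state, x, d, lam)
            w[idx] = orig - h
            down = objective(state, x, d, lam)
            w[idx] = orig
            g[idx] = (up - down) / (2 * h)
        grads.append(g)
    return grads


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == 0.5

    @given(st.floats(-30, 30))
    def test_complement_identity(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_derivative_matches_finite_difference(self):
        x, h = 1.0, 1e-6
        analytic = sigmoid(x) * (1 - sigmoid(x))
        numeric = (sigmoid(x + h) - sigmoid(x - h)) / (2 * h)
        assert abs(analytic - numeric) / analytic < 1e-8

    def test_saturates_without_error(self):
        assert sigmoid(1000.0) == 1.0 and sigmoid(-1000.0) == 0.0


class TestForward:
    def test_zero_weights_give_half_everywhere(self):
        state = random_state(seed=1)
        state.w_ih[:] = 0.0
        state.w_ho[:] = 0.0
        tr = forward(state, np.linspace(0, 1, 6))
        np.testing.assert_array_equal(tr.hidden_out, np.full(4, 0.5))
        np.testing.assert_array_equal(tr.output_out, np.full(2, 0.5))

    def test_hand_computed_two_layer_composition(self):
        # 1-1-1 chain with unit weights and x = 0: hidden 0.5, output f(0.5)
        state = NetworkState(
            w_ih=np.array([[1.0]]), w_ho=np.array([[1.0]]),
            prev_delta_ih=np.zeros((1, 1)), prev_delta_ho=np.zeros((1, 1)),
        )
        tr = forward(state, np.array([0.0]))
        assert tr.hidden_out[0] == 0.5
        assert tr.output_out[0] == pytest.approx(1 / (1 + np.exp(-0.5)))

    def test_outputs_invariant_to_hidden_permutation(self, rng):
        state = random_state(seed=2)
        x = rng.uniform(0, 1, 6)
        perm = rng.permutation(4)
        permuted = NetworkState(
            w_ih=state.w_ih[:, perm], w_ho=state.w_ho[perm, :],
            prev_delta_ih=np.zeros((6, 4)), prev_delta_ho=np.zeros((4, 2)),
        )
        np.testing.assert_allclose(
            forward(state, x).output_out, forward(permuted, x).output_out, rtol=1e-12
        )

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(DataFormatError):
            forward(random_state(), np.zeros(5))

    def test_activations_stay_in_open_unit_interval(self, rng):
        tr = forward(random_state(seed=3), rng.uniform(0, 1, 6))
        for a in (tr.hidden_out, tr.output_out):
            assert ((a > 0) & (a < 1)).all()


class TestComputeMse:
    def test_zero_residual_case(self):
        y = np.array([[0.2, 0.8], [0.6, 0.4]])
        assert compute_mse(y, y) == 0.0

    def test_single_sample_opposite_onehots(self):
        assert compute_mse(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])) == 2.0

    def test_matches_double_loop_oracle(self, rng):
        outputs = rng.uniform(0, 1, (5, 2))
        targets = rng.integers(0, 2, (5, 2)).astype(float)
        total = 0.0
        for i in range(5):
            for j in range(2):
                total += (targets[i, j] - outputs[i, j]) ** 2
        assert compute_mse(outputs, targets) == pytest.approx(total / 5, rel=1e-15)

    def test_empty_input_is_an_error(self):
        with pytest.raises(DataFormatError):
            compute_mse(np.empty((0, 2)), np.empty((0, 2)))


class TestBackpropUpdate:
    def test_bare_rule_recovered_without_momentum_and_decay(self, rng):
        state = random_state(seed=4)
        x = rng.uniform(0, 1, 6)
        d = np.array([1.0, 0.0])
        config = NetworkConfig(layer_sizes=(6, 4, 2), eta=0.7, alpha=0.0, lambda_reg=0.0)
        new = backprop_update(state, x, d, config)

        # independent bare-rule evaluation: eta*(d-O)O(1-O)O_j and its
        # backpropagated input-layer counterpart
        tr = forward(state, x)
        h, o = tr.hidden_out, tr.output_out
        dk = (d - o) * o * (1 - o)
        dj = h * (1 - h) * (state.w_ho @ dk)
        # the applied deltas are stored verbatim in the momentum memory
        np.testing.assert_array_equal(new.prev_delta_ho, 0.7 * np.outer(h, dk))
        np.testing.assert_array_equal(new.prev_delta_ih, 0.7 * np.outer(x, dj))
        np.testing.assert_allclose(new.w_ho, state.w_ho + 0.7 * np.outer(h, dk), rtol=1e-15)

    def test_zero_gradient_step_scales_previous_delta_by_alpha(self, rng):
        state = random_state(seed=5)
        state.prev_delta_ih = rng.normal(size=(6, 4))
        state.prev_delta_ho = rng.normal(size=(4, 2))
        x = rng.uniform(0, 1, 6)
        d = forward(state, x).output_out  # d == output -> gradient vanishes
        config = NetworkConfig(layer_sizes=(6, 4, 2), eta=0.5, alpha=0.9, lambda_reg=0.0)
        new = backprop_update(state, x, d, config)
        np.testing.assert_array_equal(new.prev_delta_ih, 0.9 * state.prev_delta_ih)
        np.testing.assert_array_equal(new.prev_delta_ho, 0.9 * state.prev_delta_ho)

    def test_momentum_deltas_decay_geometrically(self, rng):
        state = random_state(seed=6)
        p0 = rng.normal(size=(6, 4))
        state.prev_delta_ih = p0.copy()
        x = rng.uniform(0, 1, 6)
        config = NetworkConfig(layer_sizes=(6, 4, 2), eta=0.5, alpha=0.8, lambda_reg=0.0)
        for n in range(1, 4):
            state = backprop_update(state, x, forward(state, x).output_out, config)
            np.testing.assert_allclose(state.prev_delta_ih, 0.8**n * p0, rtol=1e-12)

    def test_weight_decay_shrinks_weights_multiplicatively(self, rng):
        state = random_state(seed=7)
        x = rng.uniform(0, 1, 6)
        config = NetworkConfig(layer_sizes=(6, 4, 2), eta=0.5, alpha=0.0, lambda_reg=0.01)
        d = forward(state, x).output_out
        new = backprop_update(state, x, d, config)
        # zero error gradient, zero momentum: w <- (1 - eta*lambda) w
        np.testing.assert_allclose(new.w_ih, (1 - 0.5 * 0.01) * state.w_ih, rtol=1e-12)
        norms = [np.linalg.norm(new.w_ih)]
        for _ in range(3):
            new = backprop_update(new, x, forward(new, x).output_out, config)
            norms.append(np.linalg.norm(new.w_ih))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_update_matches_finite_difference_gradient(self, seed):
        rng = np.random.default_rng(seed)
        state = random_state(seed=seed)
        x = rng.uniform(0, 1, 6)
        d = np.zeros(2)
        d[rng.integers(0, 2)] = 1.0
        lam, eta = 0.01, 0.5
        config = NetworkConfig(layer_sizes=(6, 4, 2), eta=eta, alpha=0.0, lambda_reg=lam)
        new = backprop_update(state, x, d, config)
        g_ih, g_ho = numeric_gradient(state, x, d, lam)
        for applied, grad in ((new.w_ih - state.w_ih, g_ih), (new.w_ho - state.w_ho, g_ho)):
            rel = np.linalg.norm(applied - (-eta * grad)) / np.linalg.norm(eta * grad)
            assert rel < 1e-6


class TestTrainBpnn:
    def test_zero_epoch_budget_is_a_noop(self, tiny_ds):
        config = NetworkConfig(max_epochs=0, seed=9)
        state, report = train_bpnn(tiny_ds, config)
        reference = init_state(config)
        np.testing.assert_array_equal(state.w_ih, reference.w_ih)
        np.testing.assert_array_equal(state.w_ho, reference.w_ho)
        assert report.mse_history.size == 0 and report.final_mse is None
        assert report.stop_reason == "epoch_budget"

    def test_identical_config_is_bit_reproducible(self, tiny_ds, tiny_config):
        a, ra = train_bpnn(tiny_ds, tiny_config)
        b, rb = train_bpnn(tiny_ds, tiny_config)
        np.testing.assert_array_equal(a.w_ih, b.w_ih)
        np.testing.assert_array_equal(a.w_ho, b.w_ho)
        np.testing.assert_array_equal(ra.mse_history, rb.mse_history)

    def test_uniform_sample_weights_reproduce_unweighted_run(self, tiny_ds, tiny_config):
        n = tiny_ds.mask("train").sum()
        a, _ = train_bpnn(tiny_ds, tiny_config)
        b, _ = train_bpnn(tiny_ds, tiny_config, sample_weights=np.full(n, 1.0 / n))
        np.testing.assert_array_equal(a.w_ih, b.w_ih)
        np.testing.assert_array_equal(a.w_ho, b.w_ho)

    def test_one_epoch_matches_sequential_single_updates(self, tiny_ds):
        """The compiled epoch kernel agrees with per-sample numpy updates."""
        config = NetworkConfig(layer_sizes=(6, 12, 2), eta=0.5, alpha=0.9,
                               lambda_reg=2.0**-25, max_epochs=1, seed=21)
        state, _ = train_bpnn(tiny_ds, config)

        X, sex = tiny_ds.subset_arrays("train")
        Y = one_hot(sex)
        order = np.random.default_rng([config.seed, 0x5EED]).permutation(len(X))
        reference = init_state(config)
        for i in order:
            reference = backprop_update(reference, X[i], Y[i], config)
        np.testing.assert_allclose(state.w_ih, reference.w_ih, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(state.w_ho, reference.w_ho, rtol=1e-10, atol=1e-14)

    def test_separable_data_reaches_perfect_training_accuracy(self, separable_ds):
        config = NetworkConfig(layer_sizes=(6, 12, 2), eta=0.5, alpha=0.9,
                               lambda_reg=0.0, max_epochs=2000, seed=7)
        _, report = train_bpnn(separable_ds, config)
        assert report.train_accuracy_pct == 100.0

    def test_mse_goal_stops_early(self, tiny_ds):
        config = NetworkConfig(max_epochs=2000, mse_goal=0.5, seed=9)
        state, report = train_bpnn(tiny_ds, config)
        assert report.stop_reason == "mse_goal"
        assert state.epoch_counter < 2000
        assert report.final_mse <= 0.5
        assert report.final_mse == report.mse_history[-1]

    def test_empty_training_split_is_an_error(self):
        ds = MeasurementDataset(
            X=np.full((4, 6), 100.0),
            sex=np.array([1, 0, 1, 0]),
            split=np.array(["test"] * 4, dtype=object),
        )
        with pytest.raises(DataFormatError):
            train_bpnn(ds, NetworkConfig(max_epochs=1))


class TestPredictEvaluate:
    def test_argmax_labels_with_male_tiebreak(self):
        state = random_state(seed=10)
        state.w_ih[:] = 0.0
        state.w_ho[:] = 0.0
        # all-zero weights -> outputs (0.5, 0.5) -> tie -> male
        label, out = predict(state, np.linspace(0, 1, 6))
        assert label == 0
        np.testing.assert_array_equal(out, [0.5, 0.5])

    def test_trained_predictions_match_vectorized_outputs(self, trained_tiny, tiny_ds, rng):
        X, _ = tiny_ds.subset_arrays("test")
        outputs = network_outputs(trained_tiny, X)
        for i in rng.choice(len(X), 5, replace=False):
            label, out = predict(trained_tiny, X[i])
            np.testing.assert_allclose(out, outputs[i], rtol=1e-12)
            assert label == (1 if out[0] > out[1] else 0)

    def test_constant_male_predictor_scores_class_ratio(self):
        raw = generate(default_spec(seed=0))  # 153 F / 114 M
        ds = MeasurementDataset(
            X=raw.X, sex=raw.sex, split=np.array(["train"] * len(raw), dtype=object)
        )
        state = random_state(shape=(6, 4, 2))
        state.w_ih[:] = 0.0
        state.w_ho[:] = 0.0  # ties everywhere -> constant male
        metrics = evaluate(state, ds, "train")
        assert metrics.accuracy_pct == pytest.approx(100 * 114 / 267, abs=1e-9)

    def test_accuracy_invariant_to_row_order(self, trained_tiny, tiny_ds, rng):
        metrics = evaluate(trained_tiny, tiny_ds, "test")
        perm = rng.permutation(len(tiny_ds))
        shuffled = MeasurementDataset(
            X=tiny_ds.X[perm], sex=tiny_ds.sex[perm], split=tiny_ds.split[perm]
        )
        again = evaluate(trained_tiny, shuffled, "test")
        assert again.accuracy_pct == metrics.accuracy_pct
        assert again.mse == pytest.approx(metrics.mse, rel=1e-12)

    def test_evaluate_empty_split_is_an_error(self, trained_tiny, tiny_ds):
        all_train = MeasurementDataset(
            X=tiny_ds.X, sex=tiny_ds.sex,
            split=np.array(["train"] * len(tiny_ds), dtype=object),
        )
        with pytest.raises(DataFormatError):
            evaluate(trained_tiny, all_train, "test")


class TestPersistence:
    def test_model_roundtrip_is_exact(self, trained_tiny, tiny_config, tiny_ds, tmp_path):
        path = tmp_path / "model.json"
        save_model(trained_tiny, tiny_config, path, normalization=tiny_ds.normalization)
        state, config, norm = load_model(path)
        np.testing.assert_array_equal(state.w_ih, trained_tiny.w_ih)
        np.testing.assert_array_equal(state.w_ho, trained_tiny.w_ho)
        np.testing.assert_array_equal(state.prev_delta_ho, trained_tiny.prev_delta_ho)
        assert config == tiny_config
        np.testing.assert_array_equal(norm.loc, tiny_ds.normalization.loc)

    def test_unversioned_payload_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(DataFormatError):
            load_model(path)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"eta": 0.0},
            {"eta": -1.0},
            {"alpha": 1.0},
            {"alpha": -0.1},
            {"lambda_reg": -1e-9},
            {"max_epochs": -1},
            {"init_scale": 0.0},
            {"layer_sizes": (6, 2)},
        ],
    )
    def test_out_of_range_hyperparameters_rejected(self, kwargs):
        with pytest.raises(DataFormatError):
            NetworkConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        config = NetworkConfig(layer_sizes=(6, 6, 2), eta=0.1, alpha=0.5, seed=4)
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(config.to_dict()))
        assert NetworkConfig.from_yaml(path) == config
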