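import numpy as np
import pytest
from scipy.special import expit

from lstmecoc.lstm import (
    FeatureVector,
    LSTMParams,
    TrainConfig,
    batch_loss_and_grads,
    compute_loss,
    extract_features,
    init_params,
    l2_penalty,
    lstm_forward,
    train_lstm,
)
from lstmecoc.recording import StepSequence

from conftest import toy_sequences


def reference_forward(X, params):
    """Independent step-by-step recurrence, written from the gate equations."""
    T = X.shape[0]
    H = params.hidden_units
    h = np.zeros(H)
    c = np.zeros(H)
    hs = []
    for t in range(T):
        x = X[t]
        f = expit(params.gate("f", "Wx") @ x + params.gate("f", "Wh") @ h
                  + params.gate("f", "b"))
        i = expit(params.gate("i", "Wx") @ x + params.gate("i", "Wh") @ h
                  + params.gate("i", "b"))
        s = np.tanh(params.gate("s", "Wx") @ x + params.gate("s", "Wh") @ h
                    + params.gate("s", "b"))
        o = expit(params.gate("o", "Wx") @ x + params.gate("o", "Wh") @ h
                  + params.gate("o", "b"))
        c = f * c + i * s
        h = o * np.tanh(c)
        hs.append(h.copy())
    scores = params.Wfc @ h + params.bfc
    return np.array(hs), scores


def small_sequence(rng):
    return StepSequence(data=rng.standard_normal((60, 63, 100)), label="mild")


class TestInit:
    def test_deterministic(self):
        a = init_params(16, seed=0)
        b = init_params(16, seed=0)
        assert np.array_equal(a.Wx, b.Wx) and np.array_equal(a.Wh, b.Wh)

    def test_recurrent_weights_orthogonal(self):
        p = init_params(8, seed=1)
        for g in ("f", "i", "s", "o"):
            R = p.gate(g, "Wh")
            assert np.allclose(R.T @ R, np.eye(8), atol=1e-6)

    def test_forget_bias_one_others_zero(self):
        p = init_params(4, seed=0)
        assert np.all(p.gate("f", "b") == 1.0)
        for g in ("i", "s", "o"):
            assert np.all(p.gate(g, "b") == 0.0)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError, match=">= 1"):
            init_params(0, seed=0)


class TestForward:
    def test_zero_params_zero_input_gives_zero_hidden(self, rng):
        p = init_params(5, seed=0)
        for name in ("Wx", "Wh", "b", "Wfc", "bfc"):
            getattr(p, name)[:] = 0.0
        seq = StepSequence(data=np.zeros((60, 63, 100)))
        hs, scores = lstm_forward(seq, p)
        assert np.all(hs == 0.0) and np.all(scores == 0.0)

    def test_matches_hand_unrolled_recurrence(self, rng):
        p = init_params(3, seed=2, input_dim=4)
        X = rng.standard_normal((2, 4))
        # drive the production path through a fake 2-step sequence by
        # calling the batch internals directly
        from lstmecoc.lstm import _forward_batch

        scores, cache = _forward_batch(X[None], p)
        hs_ref, scores_ref = reference_forward(X, p)
        assert np.allclose(cache["hs"][0], hs_ref, atol=1e-10)
        assert np.allclose(scores[0], scores_ref, atol=1e-10)

    def test_saturated_forget_gate_preserves_cell_state(self, rng):
        from lstmecoc.lstm import _forward_batch

        p = init_params(4, seed=0, input_dim=6)
        p.gate("f", "b")[:] = 30.0   # f -> 1
        p.gate("i", "Wx")[:] = 0.0   # i contributions zeroed
        p.gate("i", "Wh")[:] = 0.0
        p.gate("i", "b")[:] = -30.0  # i -> 0
        X = rng.standard_normal((1, 10, 6))
        _, cache = _forward_batch(X, p)
        assert np.allclose(cache["cs"][0, -1], 0.0, atol=1e-8)  # c stays at c_0 = 0

    def test_gate_activations_bounded(self, rng):
        from lstmecoc.lstm import _forward_batch

        p = init_params(6, seed=3, input_dim=20)
        X = 5 * rng.standard_normal((2, 15, 20))
        _, cache = _forward_batch(X, p)
        g = cache["gates"]
        H = 6
        assert np.all((g[..., :2 * H] > 0) & (g[..., :2 * H] < 1))   # f, i
        assert np.all((g[..., 3 * H:] > 0) & (g[..., 3 * H:] < 1))   # o
        assert np.all(np.abs(g[..., 2 * H:3 * H]) < 1)               # s
        assert np.all(np.abs(cache["hs"]) < 1)

    def test_shape_mismatch_rejected(self, rng):
        p = init_params(4, seed=0, input_dim=10)
        seq = small_sequence(rng)
        with pytest.raises(ValueError, match="dimension"):
            lstm_forward(seq, p)


class TestLoss:
    def test_uniform_scores_give_ln3(self):
        assert compute_loss(np.zeros(3), 0) == pytest.approx(np.log(3), abs=1e-12)

    def test_confident_correct_score(self):
        # softmax CE of (10, 0, 0) with label 0: ln(1 + 2 e^-10)
        val = compute_loss(np.array([10.0, 0.0, 0.0]), 0)
        assert val == pytest.approx(np.log(1 + 2 * np.exp(-10)), rel=1e-9)
        assert val == pytest.approx(9.08e-5, rel=0.01)

    def test_l2_term_is_additive(self):
        p = init_params(4, seed=0, input_dim=6)
        base = compute_loss(np.array([1.0, 2.0, 0.5]), 1)
        with_l2 = compute_loss(np.array([1.0, 2.0, 0.5]), 1, params=p, l2=0.01)
        assert with_l2 - base == pytest.approx(l2_penalty(p, 0.01), rel=1e-9)


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_bptt_matches_central_differences(self, seed):
        """Analytic BPTT vs numeric gradient on a tiny model (H=3, 2 steps)."""
        rng = np.random.default_rng(seed)
        p = init_params(3, seed=seed, input_dim=4)
        X = rng.standard_normal((2, 2, 4))
        y = np.array([0, 2])
        _, grads = batch_loss_and_grads(X, y, p, l2=0.001)
        eps = 1e-6
        for name in ("Wx", "Wh", "b", "Wfc", "bfc"):
            arr = getattr(p, name)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = batch_loss_and_grads(X, y, p, l2=0.001)
                arr[idx] = orig - eps
                lm, _ = batch_loss_and_grads(X, y, p, l2=0.001)
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name][idx]
                # denominator floored so finite-difference roundoff on
                # near-zero entries does not masquerade as gradient error
                denom = max(abs(num), abs(ana), 1e-4)
                assert abs(num - ana) / denom < 1e-5, (name, idx)


class TestTraining:
    def test_separable_toy_problem_reaches_perfect_training_accuracy(self):
        seqs = toy_sequences(n_per_class=3, seed=1)
        cfg = TrainConfig(epochs=8, mini_batch=3, seed=0)
        params, trace = train_lstm(seqs, cfg, H=8)
        assert all(b < a for a, b in zip(trace[:5], trace[1:6])), trace[:6]
        from lstmecoc.lstm import predict_softmax
        from lstmecoc.recording import class_index

        y = np.array([class_index(s.label) for s in seqs])
        assert np.array_equal(predict_softmax(params, seqs), y)

    def test_training_is_deterministic_given_seed(self):
        seqs = toy_sequences(n_per_class=2, seed=3)
        cfg = TrainConfig(epochs=2, seed=9)
        p1, t1 = train_lstm(seqs, cfg, H=4)
        p2, t2 = train_lstm(seqs, cfg, H=4)
        assert np.array_equal(p1.Wx, p2.Wx) and t1 == t2

    def test_missing_class_rejected(self):
        seqs = [s for s in toy_sequences(n_per_class=2) if s.label != "mild"]
        with pytest.raises(ValueError, match="every class"):
            train_lstm(seqs, TrainConfig(epochs=1), H=4)

    def test_large_l2_shrinks_weight_norms(self):
        seqs = toy_sequences(n_per_class=2, seed=5)
        norms = []
        for l2 in (0.0, 0.05):
            p, _ = train_lstm(seqs, TrainConfig(epochs=5, l2=l2, seed=4), H=4)
            norms.append(float(np.sum(p.Wx**2) + np.sum(p.Wh**2) + np.sum(p.Wfc**2)))
        assert norms[1] < norms[0]

    def test_sgd_momentum_optimizer_trains(self):
        seqs = toy_sequences(n_per_class=2, seed=2)
        cfg = TrainConfig(epochs=5, optimizer="sgd_momentum", learning_rate=0.01, seed=0)
        _, trace = train_lstm(seqs, cfg, H=4)
        assert trace[-1] < trace[0]


class TestFeatures:
    def test_feature_dimension_equals_hidden_units(self, rng):
        for H in (8, 256):
            p = init_params(H, seed=0)
            fv = extract_features(p, small_sequence(rng))
            assert fv.values.shape == (H,)

    def test_zero_model_gives_zero_features(self, rng):
        p = init_params(4, seed=0)
        for name in ("Wx", "Wh", "b", "Wfc", "bfc"):
            getattr(p, name)[:] = 0.0
        fv = extract_features(p, small_sequence(rng))
        assert np.all(fv.values == 0.0)

    def test_features_equal_last_hidden_state_row(self, rng):
        p = init_params(6, seed=1)
        seq = small_sequence(rng)
        hs, _ = lstm_forward(seq, p)
        fv = extract_features(p, seq)
        assert np.allclose(fv.values, hs[-1])

    def test_mean_pooling_flag(self, rng):
        p = init_params(6, seed=1)
        seq = small_sequence(rng)
        hs, _ = lstm_forward(seq, p)
        fv = extract_features(p, seq, pooling="mean")
        assert np.allclose(fv.values, hs.mean(axis=0))

    def test_checkpoint_round_trip(self, tmp_path):
        from lstmecoc.lstm import load_params, save_params

        p = init_params(5, seed=2, input_dim=7)
        path = tmp_path / "model.npz"
        save_params(p, path, TrainConfig(epochs=3))
        back, meta = load_params(path)
        assert np.array_equal(back.Wx, p.Wx)
        assert meta["H"] == 5 and meta["input_dim"] == 7
        assert meta["train_config"]["epochs"] == 3
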