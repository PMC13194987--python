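"""Forward-operator oracles (brute-force convolution, hand max-pool,
scalar gate-by-gate LSTM) and the build/train/predict contracts."""

import numpy as np
import pytest

from smokesense.nn.autograd import Tensor, sigmoid_np
from smokesense.nn.layers import BiLSTM, Conv1D, LSTMCell, MaxPool1D
from smokesense.nn.models import (ARCHITECTURES, ModelConfig, build_model,
                                  predict, small_config, train)

RNG = np.random.default_rng(7)


# ----------------------------------------------------------------------
# independent reference implementations

def conv1d_bruteforce(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                      kernel_span: int) -> np.ndarray:
    """Triple-loop valid convolution + bias + ReLU.

    x: (T, C); w: (kernel_span*C, F) with rows ordered (row, channel);
    returns (T - kernel_span + 1, F).
    """
    T, C = x.shape
    F = w.shape[1]
    out = np.zeros((T - kernel_span + 1, F))
    for i in range(T - kernel_span + 1):
        for f in range(F):
            acc = b[f]
            for k in range(kernel_span):
                for c in range(C):
                    acc += x[i + k, c] * w[k * C + c, f]
            out[i, f] = acc
    return np.maximum(out, 0.0)


def lstm_scalar_reference(x: np.ndarray, wf, wi, wc, wo, bf, bi, bc, bo,
                          reverse: bool = False) -> np.ndarray:
    """Gate-by-gate scalar LSTM (1 hidden unit, scalar input): each gate
    weight is a 2-vector applied to [h_prev, x_t]."""
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    h, c = 0.0, 0.0
    steps = range(len(x) - 1, -1, -1) if reverse else range(len(x))
    out = np.zeros(len(x))
    for t in steps:
        hx = np.array([h, x[t]])
        f = sig(wf @ hx + bf)
        i = sig(wi @ hx + bi)
        ct = np.tanh(wc @ hx + bc)
        o = sig(wo @ hx + bo)
        c = f * c + i * ct
        h = o * np.tanh(c)
        out[t] = h
    return out


# ----------------------------------------------------------------------
# convolution

def test_conv_hand_example_ones_kernel():
    """All-ones span-3 kernel on [1,2,3,4,5] gives [6,9,12]."""
    conv = Conv1D(1, 1, 3, np.random.default_rng(0))
    conv.w.data = np.ones((3, 1))
    conv.b.data = np.zeros(1)
    x = Tensor(np.array([1., 2., 3., 4., 5.]).reshape(1, 5, 1))
    out = conv.forward(x)
    assert np.allclose(out.data.ravel(), [6.0, 9.0, 12.0])


def test_conv_large_negative_bias_floors_to_zero():
    conv = Conv1D(2, 3, 3, np.random.default_rng(0))
    conv.b.data = np.full(3, -1e9)
    x = Tensor(RNG.standard_normal((2, 10, 2)))
    assert (conv.forward(x).data == 0.0).all()


def test_conv_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(100):
        T = int(rng.integers(5, 15))
        C = int(rng.integers(1, 4))
        F = int(rng.integers(1, 5))
        K = int(rng.integers(1, T + 1))
        conv = Conv1D(C, F, K, rng)
        conv.b.data = rng.standard_normal(F)
        x = rng.standard_normal((1, T, C))
        got = conv.forward(Tensor(x)).data[0]
        want = conv1d_bruteforce(x[0], conv.w.data, conv.b.data, K)
        assert np.allclose(got, want, atol=1e-8)


def test_conv_rejects_wrong_channel_count():
    conv = Conv1D(3, 2, 3, RNG)
    with pytest.raises(ValueError):
        conv.forward(Tensor(np.zeros((1, 10, 5))))


# ----------------------------------------------------------------------
# max-pool

def test_maxpool_hand_example():
    pool = MaxPool1D(3, 1)
    x = Tensor(np.array([1., 5., 2., 0., 3.]).reshape(1, 5, 1))
    assert np.allclose(pool.forward(x).data.ravel(), [5., 5., 3.])


def test_maxpool_constant_map_is_identity_values():
    pool = MaxPool1D(3, 1)
    x = Tensor(np.full((2, 6, 4), 1.5))
    assert (pool.forward(x).data == 1.5).all()


def test_maxpool_dominates_aligned_input():
    pool = MaxPool1D(3, 1)
    for _ in range(20):
        x = RNG.standard_normal((1, 12, 3))
        out = pool.forward(Tensor(x)).data
        for i in range(out.shape[1]):
            assert (out[0, i] >= x[0, i:i + 3].max(axis=0) - 1e-12).all()
            assert (out[0, i] >= x[0, i]).all()


def test_maxpool_window_longer_than_map():
    with pytest.raises(ValueError):
        MaxPool1D(5, 1).forward(Tensor(np.zeros((1, 3, 1))))


# ----------------------------------------------------------------------
# LSTM / BiLSTM

def _set_scalar_weights(cell: LSTMCell, wf, wi, wc, wo, bf, bi, bc, bo):
    # packed layout: columns [forget, input, candidate, output],
    # rows [h, x]
    w = np.zeros((2, 4))
    w[:, 0], w[:, 1], w[:, 2], w[:, 3] = wf, wi, wc, wo
    cell.w.data = w
    cell.b.data = np.array([bf, bi, bc, bo], dtype=float)


def test_lstm_zero_weights_give_zero_hidden_states():
    cell = LSTMCell(2, 3, np.random.default_rng(0))
    cell.w.data = np.zeros_like(cell.w.data)
    cell.b.data = np.zeros_like(cell.b.data)
    out = cell.forward(Tensor(RNG.standard_normal((2, 5, 2))))
    for h in out:
        assert (h.data == 0.0).all()


def test_lstm_matches_scalar_gate_by_gate_reference():
    rng = np.random.default_rng(5)
    for _ in range(25):
        wf, wi, wc, wo = (rng.standard_normal(2) for _ in range(4))
        bf, bi, bc, bo = (float(rng.standard_normal()) for _ in range(4))
        x = rng.standard_normal(4)
        for reverse in (False, True):
            cell = LSTMCell(1, 1, rng, reverse=reverse)
            _set_scalar_weights(cell, wf, wi, wc, wo, bf, bi, bc, bo)
            got = np.array([h.data[0, 0] for h in
                            cell.forward(Tensor(x.reshape(1, -1, 1)))])
            want = lstm_scalar_reference(x, wf, wi, wc, wo, bf, bi, bc, bo,
                                         reverse=reverse)
            assert np.allclose(got, want, atol=1e-10)


def test_reversing_input_swaps_directional_streams():
    """Running the forward cell on a reversed sequence, then reversing its
    outputs, equals running the backward cell on the original sequence."""
    rng = np.random.default_rng(8)
    for _ in range(10):
        fwd = LSTMCell(3, 4, np.random.default_rng(99), reverse=False)
        bwd = LSTMCell(3, 4, np.random.default_rng(99), reverse=True)
        x = rng.standard_normal((2, 6, 3))
        out_fwd_on_reversed = fwd.forward(Tensor(x[:, ::-1].copy()))
        out_bwd = bwd.forward(Tensor(x))
        for t in range(6):
            assert np.allclose(out_fwd_on_reversed[5 - t].data,
                               out_bwd[t].data, atol=1e-12)


def test_bilstm_output_width_and_concatenation_order():
    rng = np.random.default_rng(3)
    bi = BiLSTM(2, 3, rng)
    x = Tensor(RNG.standard_normal((2, 5, 2)))
    out = bi.forward(x)
    assert all(h.shape == (2, 6) for h in out)
    hf = bi.fwd.forward(x)
    hb = bi.bwd.forward(x)
    assert np.allclose(out[2].data[:, :3], hf[2].data)
    assert np.allclose(out[2].data[:, 3:], hb[2].data)


def test_gate_ranges_hold_on_random_passes():
    rng = np.random.default_rng(4)
    bi = BiLSTM(3, 4, rng)
    gates: list[dict] = []
    bi.forward(Tensor(RNG.standard_normal((3, 8, 3)) * 5), collect_gates=gates)
    assert gates
    for g in gates:
        for key in ("f", "i", "o"):
            assert (g[key] > 0).all() and (g[key] < 1).all()
        assert (np.abs(g["c_tilde"]) < 1).all()


# ----------------------------------------------------------------------
# build / train / predict

def test_build_accepts_nine_channel_input_and_three_dense_layers():
    model = build_model(small_config(n_channels=9))
    assert len(model.head) == 3
    out = model.forward(RNG.standard_normal((4, 25, 9)))
    assert out.shape == (4,)


def test_build_rejects_bad_configs():
    with pytest.raises(ValueError):
        ModelConfig(arch="transformer")
    with pytest.raises(ValueError):
        ModelConfig(dense_sizes=(64, 32))
    with pytest.raises(ValueError):
        ModelConfig(kernel_span=26)


@pytest.mark.parametrize("arch", ARCHITECTURES)
def test_build_is_deterministic_per_seed(arch):
    cfg = small_config(arch=arch, n_channels=3, seed=12)
    w1 = build_model(cfg).get_weights()
    w2 = build_model(cfg).get_weights()
    for a, b in zip(w1, w2):
        assert np.array_equal(a, b)
    w3 = build_model(small_config(arch=arch, n_channels=3, seed=13)).get_weights()
    assert any(not np.array_equal(a, b) for a, b in zip(w1, w3))


def _separable_data(n=120, amplitude=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 25, 3))
    y = np.array([0, 1] * (n // 2))
    t = np.arange(25)
    X[y == 1] += amplitude * np.sin(2 * np.pi * t / 5)[None, :, None]
    return X, y


def test_training_reaches_high_accuracy_on_separable_data():
    X, y = _separable_data()
    cfg = small_config(arch="1dcnn-bilstm", n_channels=3, epochs=30, seed=0)
    model = train(build_model(cfg), X, y)
    _, y_hat = predict(model, X)
    assert (y_hat == y).mean() >= 0.95


def test_training_stays_at_chance_on_labelless_noise():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((200, 25, 3))
    y = np.array([0, 1] * 100)
    cfg = small_config(arch="1dcnn", n_channels=3, epochs=15, seed=0)
    model = train(build_model(cfg), X[:150], y[:150])
    _, y_hat = predict(model, X[150:])
    assert 0.3 <= (y_hat == y[150:]).mean() <= 0.7


def test_training_is_seeded_deterministic():
    X, y = _separable_data(n=60)
    cfg = small_config(arch="bilstm", n_channels=3, epochs=5, seed=3)
    w1 = train(build_model(cfg), X, y).get_weights()
    w2 = train(build_model(cfg), X, y).get_weights()
    for a, b in zip(w1, w2):
        assert np.array_equal(a, b)


def test_training_rejects_single_class():
    X = np.zeros((20, 25, 3))
    with pytest.raises(ValueError, match="both classes"):
        train(build_model(small_config(n_channels=3)), X, np.zeros(20))


def test_loss_history_improves_from_start():
    X, y = _separable_data(n=80)
    cfg = small_config(arch="1dcnn", n_channels=3, epochs=20, seed=0)
    model = train(build_model(cfg), X, y)
    hist = model.history["val_loss"]
    assert min(hist) <= hist[0]
    # best-so-far sequence is non-increasing by construction; the training
    # loss must show actual learning on separable data
    assert model.history["train_loss"][-1] < model.history["train_loss"][0]


def test_predict_scores_and_threshold_consistency():
    X, y = _separable_data(n=40)
    cfg = small_config(arch="lstm", n_channels=3, epochs=5, seed=0)
    model = train(build_model(cfg), X, y)
    scores, labels = predict(model, X, threshold=0.5)
    assert ((scores >= 0) & (scores <= 1)).all()
    assert np.array_equal(labels, (scores >= 0.5).astype(int))
    _, all_pos = predict(model, X, threshold=0.0)
    assert (all_pos == 1).all()


@pytest.mark.parametrize("arch", ARCHITECTURES)
@pytest.mark.parametrize("n_channels", [1, 3, 9, 11])
def test_every_architecture_handles_every_channel_width(arch, n_channels):
    cfg = small_config(arch=arch, n_channels=n_channels, epochs=1)
    model = build_model(cfg)
    out = model.forward(RNG.standard_normal((2, 25, n_channels)))
    assert out.shape == (2,)


def test_checkpoint_round_trip(tmp_path):
    from smokesense.nn.models import load_model, save_model
    X, y = _separable_data(n=40)
    cfg = small_config(arch="1dcnn-bilstm", n_channels=3, epochs=3, seed=1)
    model = train(build_model(cfg), X, y)
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    s1, _ = predict(model, X)
    s2, _ = predict(back, X)
    assert np.allclose(s1, s2, atol=1e-12)
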