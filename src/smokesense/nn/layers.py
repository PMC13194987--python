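"""Layers for the sensor-window sequence classifiers.

All layers operate on batched tensors: inputs are (B, T, C) windows with
T=25 rows.  Convolution is 'valid' (no padding) along the row axis; the
max-pool slides a window of 3 with configurable stride; the LSTM follows
the standard gate formulation (forget/input/output gates and a tanh
candidate), and the bidirectional wrapper concatenates the forward and
backward hidden sequences per step.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


def _windows_index(length: int, span: int, stride: int = 1) -> np.ndarray:
    """(P, span) gather index for sliding windows over an axis of ``length``."""
    starts = np.arange(0, length - span + 1, stride)
    return starts[:, None] + np.arange(span)[None, :]


class Layer:
    def parameters(self) -> list[Tensor]:
        return []


class Conv1D(Layer):
    """Valid 1-D convolution over the row axis with per-filter bias and
    ReLU activation; output length T - kernel_span + 1."""

    def __init__(self, in_channels: int, n_filters: int, kernel_span: int,
                 rng: np.random.Generator):
        self.in_channels = in_channels
        self.n_filters = n_filters
        self.kernel_span = kernel_span
        fan_in = kernel_span * in_channels
        scale = np.sqrt(2.0 / fan_in)            # He init for ReLU
        self.w = Tensor(rng.standard_normal((fan_in, n_filters)) * scale,
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_filters), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        batch, length, channels = x.shape
        if channels != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {channels}")
        if self.kernel_span > length:
            raise ValueError("kernel span exceeds window length")
        idx = _windows_index(length, self.kernel_span)
        out_len = idx.shape[0]
        patches = x.take_windows(idx)                       # (B, P, K, C)
        flat = patches.reshape(batch * out_len, self.kernel_span * channels)
        conv = flat @ self.w + self.b
        return conv.reshape(batch, out_len, self.n_filters).relu()

    def parameters(self):
        return [self.w, self.b]

    def l2_penalty(self, coeff: float) -> Tensor:
        return (self.w * self.w).sum() * coeff


class BatchNorm(Layer):
    """Normalise each feature over the batch and row axes; running
    statistics are used outside training."""

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 1), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            norm = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            norm = ((x - self.running_mean[None, None, :])
                    * (self.running_var[None, None, :] + self.eps) ** -0.5)
        return norm * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class MaxPool1D(Layer):
    """Sliding maximum of window 3 (stride 1 by default) per filter."""

    def __init__(self, window: int = 3, stride: int = 1):
        self.window = window
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        _, length, _ = x.shape
        if self.window > length:
            raise ValueError("pool window exceeds feature-map length")
        idx = _windows_index(length, self.window, self.stride)
        return x.take_windows(idx).max(axis=2)              # (B, P, F)


class LSTMCell(Layer):
    """One direction of an LSTM over (B, T, F) input.

    Gates use a single packed weight matrix over [h_{prev}, x_t]; the
    forget-gate bias starts at 1 (standard recurrent practice).
    """

    def __init__(self, in_features: int, hidden_size: int,
                 rng: np.random.Generator, reverse: bool = False):
        self.in_features = in_features
        self.hidden_size = hidden_size
        self.reverse = reverse
        scale = 1.0 / np.sqrt(in_features + hidden_size)
        self.w = Tensor(rng.standard_normal(
            (in_features + hidden_size, 4 * hidden_size)) * scale,
            requires_grad=True)
        bias = np.zeros(4 * hidden_size)
        bias[:hidden_size] = 1.0                 # forget gate
        self.b = Tensor(bias, requires_grad=True)

    def forward(self, x: Tensor, collect_gates: list | None = None) -> list[Tensor]:
        """Return the hidden state per input step (in input order)."""
        batch, steps, _ = x.shape
        h = Tensor(np.zeros((batch, self.hidden_size)))
        c = Tensor(np.zeros((batch, self.hidden_size)))
        outputs: list[Tensor] = [None] * steps
        order = range(steps - 1, -1, -1) if self.reverse else range(steps)
        hs = self.hidden_size
        for t in order:
            x_t = x.take_windows(np.array([[t]])).reshape(batch, self.in_features)
            z = h.concat(x_t, axis=1) @ self.w + self.b
            # split the packed pre-activations into the three gates + candidate
            f_t = _slice_cols(z, 0, hs).sigmoid()
            i_t = _slice_cols(z, hs, 2 * hs).sigmoid()
            c_tilde = _slice_cols(z, 2 * hs, 3 * hs).tanh()
            o_t = _slice_cols(z, 3 * hs, 4 * hs).sigmoid()
            c = f_t * c + i_t * c_tilde
            h = o_t * c.tanh()
            outputs[t] = h
            if collect_gates is not None:
                collect_gates.append(
                    {"f": f_t.data, "i": i_t.data, "o": o_t.data,
                     "c_tilde": c_tilde.data})
        return outputs

    def parameters(self):
        return [self.w, self.b]


def _slice_cols(x: Tensor, start: int, stop: int) -> Tensor:
    """Differentiable column slice of a 2-D tensor."""
    def backward(g):
        if x.requires_grad:
            grad = np.zeros(x.shape)
            grad[:, start:stop] = g
            x._accumulate(grad)
    return x._make(x.data[:, start:stop], (x,), backward)


class BiLSTM(Layer):
    """Forward and backward LSTM passes; per-step output is the
    concatenation [h_forward, h_backward] (width 2 x hidden)."""

    def __init__(self, in_features: int, hidden_size: int,
                 rng: np.random.Generator):
        self.fwd = LSTMCell(in_features, hidden_size, rng, reverse=False)
        self.bwd = LSTMCell(in_features, hidden_size, rng, reverse=True)
        self.hidden_size = hidden_size

    def forward(self, x: Tensor, collect_gates: list | None = None) -> list[Tensor]:
        hf = self.fwd.forward(x, collect_gates)
        hb = self.bwd.forward(x, collect_gates)
        return [f.concat(b, axis=1) for f, b in zip(hf, hb)]

    def final_state(self, x: Tensor, collect_gates: list | None = None) -> Tensor:
        """[last forward hidden state, last backward hidden state]."""
        hf = self.fwd.forward(x, collect_gates)
        hb = self.bwd.forward(x, collect_gates)
        return hf[-1].concat(hb[0], axis=1)

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, activation: str = "relu"):
        scale = np.sqrt(2.0 / in_features) if activation == "relu" \
            else 1.0 / np.sqrt(in_features)
        self.w = Tensor(rng.standard_normal((in_features, out_features)) * scale,
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.w + self.b
        if self.activation == "relu":
            return out.relu()
        if self.activation == "linear":
            return out
        raise ValueError(f"unknown activation {self.activation!r}")

    def parameters(self):
        return [self.w, self.b]


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
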