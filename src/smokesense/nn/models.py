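"""The four window classifiers and their training/prediction contracts.

Architectures (all ending in the same 3-layer dense head and a single
sigmoid output):

* ``lstm``          — unidirectional LSTM over the 25 rows, last hidden state;
* ``1dcnn``         — conv(ReLU) -> batch norm -> max-pool -> flatten;
* ``bilstm``        — bidirectional LSTM, concatenated final states;
* ``1dcnn-bilstm``  — conv(ReLU) -> batch norm -> max-pool -> BiLSTM ->
                      concatenated final states.

Training is mini-batch Adam on binary cross-entropy with an L2 penalty on
the convolution weights, a held-out validation fraction for early
stopping, and per-channel z-scoring using training-set statistics only.
Everything is seeded and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .autograd import Tensor, bce_with_logits, sigmoid_np
from .layers import Adam, BatchNorm, BiLSTM, Conv1D, Dense, LSTMCell, MaxPool1D

ARCHITECTURES = ("lstm", "1dcnn", "bilstm", "1dcnn-bilstm")


@dataclass
class ModelConfig:
    arch: str = "1dcnn-bilstm"
    n_channels: int = 9
    window_rows: int = 25
    n_filters: int = 128
    kernel_span: int = 11          # 11-row receptive field
    pool_window: int = 3
    pool_stride: int = 1
    hidden_size: int = 64
    dense_sizes: tuple[int, int, int] = (64, 32, 1)
    l2_coeff: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    patience: int = 10
    validation_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.arch!r}; "
                             f"choose from {ARCHITECTURES}")
        if len(self.dense_sizes) != 3 or self.dense_sizes[-1] != 1:
            raise ValueError("dense head must have exactly 3 layers ending in 1")
        if self.kernel_span > self.window_rows:
            raise ValueError("kernel_span exceeds window length")


#: compact configuration for quick experiments on small synthetic cohorts
def small_config(**overrides) -> ModelConfig:
    base = ModelConfig(n_filters=16, hidden_size=12, dense_sizes=(24, 12, 1),
                       epochs=40, patience=8)
    return replace(base, **overrides)


class Model:
    """A built (possibly trained) classifier."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.conv = self.bn = self.pool = None
        self.lstm = self.bilstm = None
        head_in = None
        if c.arch in ("1dcnn", "1dcnn-bilstm"):
            self.conv = Conv1D(c.n_channels, c.n_filters, c.kernel_span, rng)
            self.bn = BatchNorm(c.n_filters)
            self.pool = MaxPool1D(c.pool_window, c.pool_stride)
            conv_len = c.window_rows - c.kernel_span + 1
            pool_len = (conv_len - c.pool_window) // c.pool_stride + 1
            if c.arch == "1dcnn":
                head_in = pool_len * c.n_filters
            else:
                self.bilstm = BiLSTM(c.n_filters, c.hidden_size, rng)
                head_in = 2 * c.hidden_size
        elif c.arch == "bilstm":
            self.bilstm = BiLSTM(c.n_channels, c.hidden_size, rng)
            head_in = 2 * c.hidden_size
        elif c.arch == "lstm":
            self.lstm = LSTMCell(c.n_channels, c.hidden_size, rng)
            head_in = c.hidden_size
        self.head = [
            Dense(head_in, c.dense_sizes[0], rng, "relu"),
            Dense(c.dense_sizes[0], c.dense_sizes[1], rng, "relu"),
            Dense(c.dense_sizes[1], c.dense_sizes[2], rng, "linear"),
        ]
        # z-score statistics, fitted at training time
        self.norm_mean = np.zeros(c.n_channels)
        self.norm_std = np.ones(c.n_channels)
        self.history: dict[str, list[float]] = {}

    # ------------------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in (self.conv, self.bn, self.lstm, self.bilstm, *self.head):
            if layer is not None:
                params.extend(layer.parameters())
        return params

    def forward(self, x: np.ndarray, training: bool = False,
                collect_gates: list | None = None) -> Tensor:
        """Logits for a batch of raw windows (B, T, C)."""
        if x.ndim != 3 or x.shape[2] != self.config.n_channels:
            raise ValueError(
                f"expected (B, {self.config.window_rows}, "
                f"{self.config.n_channels}) input, got {x.shape}")
        z = (x - self.norm_mean) / self.norm_std
        t = Tensor(z)
        if self.conv is not None:
            t = self.conv.forward(t)
            t = self.bn.forward(t, training=training)
            t = self.pool.forward(t)
        if self.bilstm is not None:
            t = self.bilstm.final_state(t, collect_gates)
        elif self.lstm is not None:
            t = self.lstm.forward(t, collect_gates)[-1]
        else:
            b = t.shape[0]
            t = t.reshape(b, int(np.prod(t.shape[1:])))
        for layer in self.head:
            t = layer.forward(t)
        return t.reshape(t.shape[0])

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()


def build_model(config: ModelConfig) -> Model:
    """Construct a model with seeded parameter initialisation."""
    return Model(config)


def train(model: Model, X: np.ndarray, y: np.ndarray) -> Model:
    """Fit in place with Adam + early stopping; returns the model.

    Requires both classes in ``y``.  A validation fraction is carved from
    the training data (seeded); the parameters of the best validation epoch
    are restored at the end.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    c = model.config
    rng = np.random.default_rng(np.random.SeedSequence([c.seed, 7]))

    flat = X.reshape(-1, X.shape[2])
    model.norm_mean = flat.mean(axis=0)
    model.norm_std = np.maximum(flat.std(axis=0), 1e-8)

    n = len(y)
    perm = rng.permutation(n)
    n_val = max(int(round(c.validation_frac * n)), 1) if n >= 10 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = Adam(model.parameters(), lr=c.learning_rate)
    best_loss, best_weights, best_epoch = np.inf, model.get_weights(), -1
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(c.epochs):
        order = rng.permutation(len(ytr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), c.batch_size):
            batch = order[start:start + c.batch_size]
            if len(batch) < 2:       # batch norm needs >1 row
                continue
            opt.zero_grad()
            logits = model.forward(Xtr[batch], training=True)
            loss = bce_with_logits(logits, ytr[batch])
            if model.conv is not None and c.l2_coeff > 0:
                loss = loss + model.conv.l2_penalty(c.l2_coeff)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        if n_val:
            val_logits = model.forward(Xval, training=False)
            val_loss = float(bce_with_logits(val_logits, yval).data)
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, best_weights, best_epoch = val_loss, model.get_weights(), epoch
        elif epoch - best_epoch >= c.patience:
            break
    model.set_weights(best_weights)
    model.history = history
    return model


def predict(model: Model, X: np.ndarray,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-window probability in [0,1] and thresholded hard label."""
    scores = np.empty(len(X))
    for start in range(0, len(X), 256):
        logits = model.forward(X[start:start + 256], training=False)
        scores[start:start + 256] = sigmoid_np(logits.data)
    return scores, (scores >= threshold).astype(int)


def save_model(model: Model, path: str | Path) -> None:
    """Portable checkpoint: npz weights + JSON sidecar with the config."""
    path = Path(path)
    weights = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    if model.bn is not None:
        weights["bn_mean"] = model.bn.running_mean
        weights["bn_var"] = model.bn.running_var
    weights["norm_mean"] = model.norm_mean
    weights["norm_std"] = model.norm_std
    np.savez(path.with_suffix(".npz"), **weights)
    sidecar = asdict(model.config)
    sidecar["dense_sizes"] = list(model.config.dense_sizes)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> Model:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["dense_sizes"] = tuple(cfg["dense_sizes"])
    model = Model(ModelConfig(**cfg))
    data = np.load(path.with_suffix(".npz"))
    model.set_weights([data[f"w{i}"] for i in range(len(model.parameters()))])
    if model.bn is not None:
        model.bn.running_mean = data["bn_mean"]
        model.bn.running_var = data["bn_var"]
    model.norm_mean = data["norm_mean"]
    model.norm_std = data["norm_std"]
    return model
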