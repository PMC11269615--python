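"""1D convolutional-recurrent feature extractor, implemented from scratch.

Architecture (one block, exactly as parameter-counted in the model's
bookkeeping): a 1-D convolution with 16 length-8 kernels shared across the
14 channels (right zero-padding of k-1 = 7 keeps the length at 128), batch
normalization per kernel, ReLU, size-2 stride-1 max pooling (zero-padded at
the right edge), dropout (p = 0.5), then the 14 x 128 x 16 activation tensor
is flattened to 28,672 values and fed as a single time-step into an LSTM
with 32 units.  A softmax head drives end-to-end training; after training
the 32-dimensional LSTM hidden state is the frozen feature vector handed to
the downstream classifier.

Parameter accounting: conv 16 x (8 + 1) = 144, batch norm 16 x 2 = 32,
LSTM 4*32 x (28,672 + 32 + 1) = 3,674,240, head 4 x (32 + 1) = 132.

Everything is NumPy: forward passes, backpropagation and the Adam optimizer
are written out explicitly so that each stage can be checked against
brute-force oracles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

DTYPE = np.float32


@dataclass(frozen=True)
class CRNNConfig:
    """Architecture and training hyperparameters (defaults = replication)."""

    n_channels: int = 14
    segment_len: int = 128
    n_filters: int = 16
    kernel_size: int = 8
    stride: int = 1
    pool_size: int = 2
    pool_stride: int = 1
    dropout_p: float = 0.5
    lstm_units: int = 32
    n_classes: int = 4
    epochs: int = 90
    batch_size: int = 240
    learning_rate: float = 1e-3
    grad_decay: float = 0.99   # second-moment (squared-gradient) decay of Adam
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size > self.segment_len:
            raise ValueError("kernel_size must not exceed segment length")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    @property
    def flat_dim(self) -> int:
        return self.n_channels * self.segment_len * self.n_filters


def output_length(v: int, p: int, k: int, sl: int) -> int:
    """Sequence length after a sliding window: floor((v + p - k)/sl) + 1."""
    if sl < 1:
        raise ValueError("stride must be >= 1")
    if v + p < k:
        raise ValueError("padded input shorter than the kernel")
    return (v + p - k) // sl + 1


def count_parameters(config: CRNNConfig = CRNNConfig()) -> dict[str, int]:
    """Learnable-parameter count per layer."""
    u, d = config.lstm_units, config.flat_dim
    counts = {
        "conv": config.n_filters * (config.kernel_size + 1),
        "batchnorm": 2 * config.n_filters,
        "lstm": 4 * u * (d + u + 1),
        "head": config.n_classes * (u + 1),
    }
    counts["total"] = sum(counts.values())
    return counts


@dataclass
class CRNNParams:
    """All learnable parameters plus batch-norm running statistics.

    LSTM matrices are gate-stacked in the order input, forget, cell, output:
    ``lstm_W`` is (4u x d), ``lstm_R`` (4u x u), ``lstm_b`` (4u,).
    """

    conv_w: np.ndarray
    conv_b: np.ndarray
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray
    lstm_W: np.ndarray
    lstm_R: np.ndarray
    lstm_b: np.ndarray
    head_W: np.ndarray
    head_b: np.ndarray

    def trainable(self) -> dict[str, np.ndarray]:
        return {
            "conv_w": self.conv_w, "conv_b": self.conv_b,
            "bn_gamma": self.bn_gamma, "bn_beta": self.bn_beta,
            "lstm_W": self.lstm_W, "lstm_R": self.lstm_R, "lstm_b": self.lstm_b,
            "head_W": self.head_W, "head_b": self.head_b,
        }

    def save(self, path: str | Path, config: CRNNConfig | None = None) -> None:
        arrays = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        if config is not None:
            arrays["_config_json"] = np.frombuffer(
                repr(dataclasses.asdict(config)).encode(), dtype=np.uint8
            )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CRNNParams":
        with np.load(path) as z:
            return cls(**{
                f.name: z[f.name] for f in dataclasses.fields(cls)
            })


def init_params(config: CRNNConfig) -> CRNNParams:
    """Glorot conv/head and LSTM input weights, orthogonal recurrent weights,
    zero biases except a unit forget-gate bias."""
    rng = np.random.default_rng(config.seed)
    k, nf, u, d = config.kernel_size, config.n_filters, config.lstm_units, config.flat_dim

    def glorot_uniform(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    lstm_W = rng.normal(0.0, np.sqrt(2.0 / (d + u)), size=(4 * u, d))
    # Orthogonal recurrent initializer, gate by gate.
    blocks = []
    for _ in range(4):
        a = rng.standard_normal((u, u))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    lstm_R = np.vstack(blocks)
    lstm_b = np.zeros(4 * u)
    lstm_b[u : 2 * u] = 1.0  # unit forget-gate bias

    return CRNNParams(
        conv_w=glorot_uniform((nf, k), k, k).astype(DTYPE),
        conv_b=np.zeros(nf, dtype=DTYPE),
        bn_gamma=np.ones(nf, dtype=DTYPE),
        bn_beta=np.zeros(nf, dtype=DTYPE),
        bn_mean=np.zeros(nf, dtype=DTYPE),
        bn_var=np.ones(nf, dtype=DTYPE),
        lstm_W=lstm_W.astype(DTYPE),
        lstm_R=lstm_R.astype(DTYPE),
        lstm_b=lstm_b.astype(DTYPE),
        head_W=glorot_uniform((config.n_classes, u), u, config.n_classes).astype(DTYPE),
        head_b=np.zeros(config.n_classes, dtype=DTYPE),
    )


# ---------------------------------------------------------------------------
# Layer forward passes

def conv1d_same(
    segment: np.ndarray, weights: np.ndarray, biases: np.ndarray
) -> np.ndarray:
    """Channel-shared 1-D convolution with trailing zero padding.

    ``segment`` is (..., C, V); each of the F kernels slides over every
    channel independently with the same weights.  The input is right-padded
    with k-1 zeros so the output is (..., C, V, F) with the length preserved.
    """
    x = np.asarray(segment)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    k = weights.shape[1]
    xpad = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(0, k - 1)])
    windows = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=-1)
    out = np.einsum("bcvk,fk->bcvf", windows, weights, optimize=True) + biases
    return out[0] if squeeze else out


def batchnorm_forward(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    mode: str = "train",
    running: tuple[np.ndarray, np.ndarray] | None = None,
    momentum: float = 0.1,
    eps: float = 1e-5,
    literal_variance_denominator: bool = False,
):
    """Per-kernel batch normalization over a (B, C, V, F) activation tensor.

    Train mode standardizes each kernel's activations by the batch mean and
    variance over (B, C, V) and updates the running statistics in place;
    eval mode uses the running statistics.  The denominator is
    sqrt(var + eps) by default; ``literal_variance_denominator`` divides by
    (var + eps) instead, reproducing the normalization equation exactly as
    printed for fidelity experiments.

    Returns ``(out, cache)`` where cache holds what backprop needs.
    """
    if mode == "train":
        if x.shape[0] < 2:
            raise ValueError("batch normalization needs batch size >= 2 in train mode")
        axes = tuple(range(x.ndim - 1))
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        if running is not None:
            r_mean, r_var = running
            r_mean *= 1 - momentum
            r_mean += momentum * mean.astype(r_mean.dtype)
            r_var *= 1 - momentum
            r_var += momentum * var.astype(r_var.dtype)
    elif mode == "eval":
        if running is None:
            raise ValueError("eval mode requires running statistics")
        mean, var = running
    else:
        raise ValueError(f"unknown mode {mode!r}")
    denom = (var + eps) if literal_variance_denominator else np.sqrt(var + eps)
    xhat = (x - mean) / denom
    out = gamma * xhat + beta
    cache = (xhat, denom, gamma)
    return out, cache


def activation(x: np.ndarray, kind: str = "relu") -> np.ndarray:
    """Element-wise sigmoid, tanh or rectified-linear activation."""
    if kind == "sigmoid":
        return _sigmoid(x)
    if kind == "tanh":
        return np.tanh(x)
    if kind == "relu":
        return np.maximum(0, x)
    raise ValueError(f"unknown activation kind {kind!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def maxpool_same(x: np.ndarray, axis: int = -2) -> np.ndarray:
    """Size-2 stride-1 max pooling along ``axis`` with a zero pad at the end.

    mp_v = max(x_v, x_{v+1}); the final position compares against zero, so
    the output length equals the input length.
    """
    x = np.asarray(x)
    shifted = np.roll(x, -1, axis=axis)
    idx = [slice(None)] * x.ndim
    idx[axis % x.ndim] = -1
    shifted[tuple(idx)] = 0
    return np.maximum(x, shifted)


def dropout(
    x: np.ndarray,
    p: float = 0.5,
    rng: np.random.Generator | None = None,
    mode: str = "train",
):
    """Inverted dropout: train zeroes units w.p. ``p`` and rescales survivors
    by 1/(1-p); eval is the identity.  Returns ``(out, mask)``."""
    if mode == "eval" or p == 0:
        return x, None
    if rng is None:
        raise ValueError("train-mode dropout requires an rng")
    mask = (rng.random(x.shape, dtype=np.float32) >= p).astype(x.dtype) / (1.0 - p)
    return x * mask, mask


def lstm_step(
    x: np.ndarray,
    W: np.ndarray,
    R: np.ndarray,
    b: np.ndarray,
    h0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
):
    """One LSTM step on a (B, d) batch; gates stacked [input, forget, cell, output].

    Gate activations are sigmoid, state activations tanh.  Returns
    ``(h, cache)``.
    """
    u = R.shape[1]
    B = x.shape[0]
    if h0 is None:
        h0 = np.zeros((B, u), dtype=x.dtype)
    if c0 is None:
        c0 = np.zeros((B, u), dtype=x.dtype)
    z = x @ W.T + h0 @ R.T + b
    i = _sigmoid(z[:, :u])
    f = _sigmoid(z[:, u : 2 * u])
    g = np.tanh(z[:, 2 * u : 3 * u])
    o = _sigmoid(z[:, 3 * u :])
    c = f * c0 + i * g
    tc = np.tanh(c)
    h = o * tc
    cache = (x, h0, c0, i, f, g, o, tc)
    return h, cache


def lstm_features(flattened: np.ndarray, params: CRNNParams) -> np.ndarray:
    """LSTM hidden state after one step on the flattened activation vector(s)."""
    x = np.atleast_2d(np.asarray(flattened, dtype=DTYPE))
    d = params.lstm_W.shape[1]
    if x.shape[1] != d:
        raise ValueError(f"flattened input must have length {d}, got {x.shape[1]}")
    h, _ = lstm_step(x, params.lstm_W, params.lstm_R, params.lstm_b)
    return h[0] if np.asarray(flattened).ndim == 1 else h


# ---------------------------------------------------------------------------
# Full forward / backward

def _forward(
    X: np.ndarray,
    params: CRNNParams,
    config: CRNNConfig,
    mode: str,
    rng: np.random.Generator | None = None,
):
    """Forward pass through the whole network; returns logits, features, cache."""
    B = X.shape[0]
    a_conv = conv1d_same(X, params.conv_w, params.conv_b)
    assert a_conv.shape == (B, config.n_channels, config.segment_len, config.n_filters)
    a_bn, bn_cache = batchnorm_forward(
        a_conv, params.bn_gamma, params.bn_beta, mode=mode,
        running=(params.bn_mean, params.bn_var),
        momentum=config.bn_momentum, eps=config.bn_eps,
    )
    a_relu = np.maximum(0, a_bn)
    a_pool = maxpool_same(a_relu, axis=2)
    a_drop, drop_mask = dropout(a_pool, config.dropout_p, rng, mode)
    flat = a_drop.reshape(B, -1)
    h, lstm_cache = lstm_step(flat, params.lstm_W, params.lstm_R, params.lstm_b)
    logits = h @ params.head_W.T + params.head_b
    cache = (X, a_bn, a_relu, a_pool, drop_mask, flat, h, bn_cache, lstm_cache)
    return logits, h, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _backward(
    dlogits: np.ndarray, params: CRNNParams, config: CRNNConfig, cache
) -> dict[str, np.ndarray]:
    X, a_bn, a_relu, a_pool, drop_mask, flat, h, bn_cache, lstm_cache = cache
    B = X.shape[0]
    grads: dict[str, np.ndarray] = {}

    # Head
    grads["head_W"] = dlogits.T @ h
    grads["head_b"] = dlogits.sum(axis=0)
    dh = dlogits @ params.head_W

    # LSTM (single step from zero state: c = i*g, h = o*tanh(c))
    x_in, h0, c0, i, f, g, o, tc = lstm_cache
    u = config.lstm_units
    do = dh * tc
    dc = dh * o * (1 - tc * tc)
    di = dc * g
    dg = dc * i
    df = dc * c0  # zero for a zero initial cell state
    dz = np.concatenate(
        [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
        axis=1,
    )
    grads["lstm_W"] = dz.T @ x_in
    grads["lstm_R"] = dz.T @ h0
    grads["lstm_b"] = dz.sum(axis=0)
    dflat = dz @ params.lstm_W

    dpool = dflat.reshape(a_pool.shape)
    if drop_mask is not None:
        dpool = dpool * drop_mask

    # Max-pool backward: route each output gradient to its winning input.
    shifted = np.roll(a_relu, -1, axis=2)
    shifted[:, :, -1, :] = 0
    left_wins = a_relu >= shifted
    drelu = np.where(left_wins, dpool, 0)
    drelu[:, :, 1:, :] += np.where(~left_wins, dpool, 0)[:, :, :-1, :]

    dbn = drelu * (a_bn > 0)

    # Batch norm backward (train mode statistics).
    xhat, denom, gamma = bn_cache
    axes = (0, 1, 2)
    n = B * config.n_channels * config.segment_len
    grads["bn_gamma"] = (dbn * xhat).sum(axis=axes)
    grads["bn_beta"] = dbn.sum(axis=axes)
    dxhat = dbn * gamma
    dconv = (
        dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
    ) / denom

    # Convolution backward (input gradient not needed).
    k = config.kernel_size
    xpad = np.pad(X, [(0, 0), (0, 0), (0, k - 1)])
    windows = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=-1)
    grads["conv_w"] = np.einsum("bcvf,bcvk->fk", dconv, windows, optimize=True)
    grads["conv_b"] = dconv.sum(axis=(0, 1, 2))
    return grads


@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "epoch": np.arange(1, len(self.epoch_loss) + 1),
            "loss": self.epoch_loss,
            "train_acc": self.epoch_accuracy,
            "val_acc": self.val_accuracy or [np.nan] * len(self.epoch_loss),
        })
        df.to_csv(path, index=False)


def train_crnn(
    X: np.ndarray,
    y: np.ndarray,
    config: CRNNConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[CRNNParams, TrainingHistory]:
    """End-to-end training of the extractor + softmax head with Adam.

    ``X`` is (n, 14, 128) and ``y`` integer class indices.  Deterministic
    given ``config.seed``.  Raises if the loss becomes non-finite.
    """
    X = np.asarray(X, dtype=DTYPE)
    y = np.asarray(y)
    n = X.shape[0]
    params = init_params(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    trainable = params.trainable()
    m_t = {k: np.zeros_like(v) for k, v in trainable.items()}
    v_t = {k: np.zeros_like(v) for k, v in trainable.items()}
    beta1, beta2, eps = 0.9, config.grad_decay, 1e-8
    step = 0
    history = TrainingHistory()

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue  # batch norm needs at least two samples
            xb, yb = X[idx], y[idx]
            logits, _, cache = _forward(xb, params, config, "train", rng)
            probs = _softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}: {loss}"
                )
            losses.append(float(loss) * len(yb))
            correct += int((probs.argmax(axis=1) == yb).sum())
            seen += len(yb)

            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = _backward(dlogits.astype(DTYPE), params, config, cache)

            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for name, p in trainable.items():
                g = grads[name].astype(p.dtype, copy=False)
                m, v = m_t[name], v_t[name]
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                p -= lr_t * m / (np.sqrt(v) + eps)

        history.epoch_loss.append(sum(losses) / max(seen, 1))
        history.epoch_accuracy.append(correct / max(seen, 1))
        if validation is not None:
            xv, yv = validation
            pred = predict_classes(xv, params, config)
            history.val_accuracy.append(float((pred == yv).mean()))
    return params, history


def extract_features(
    X: np.ndarray, params: CRNNParams, config: CRNNConfig, batch_size: int = 512
) -> np.ndarray:
    """Eval-mode forward pass to the 32-dimensional LSTM feature vector."""
    X = np.asarray(X, dtype=DTYPE)
    out = np.empty((X.shape[0], config.lstm_units), dtype=DTYPE)
    for start in range(0, X.shape[0], batch_size):
        xb = X[start : start + batch_size]
        _, h, _ = _forward(xb, params, config, "eval")
        out[start : start + len(xb)] = h
    return out


def predict_classes(
    X: np.ndarray, params: CRNNParams, config: CRNNConfig, batch_size: int = 512
) -> np.ndarray:
    """Softmax-head class predictions in eval mode."""
    X = np.asarray(X, dtype=DTYPE)
    preds = np.empty(X.shape[0], dtype=np.int64)
    for start in range(0, X.shape[0], batch_size):
        xb = X[start : start + batch_size]
        logits, _, _ = _forward(xb, params, config, "eval")
        preds[start : start + len(xb)] = logits.argmax(axis=1)
    return preds
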