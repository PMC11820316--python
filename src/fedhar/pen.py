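"""Perceptive extraction network (PEN).

A dual-branch extractor for windowed multi-channel sensor sequences:

* Feature Network — three convolutional blocks (1-D convolution with
  "same" padding, batch normalization, leaky-ReLU), capturing local
  short-term patterns; temporal mean pooling yields a fixed-size vector.
* Relation Network — an LSTM layer followed by a GRU layer, then
  scaled-free dot-product self-attention over the GRU output sequence
  (Query, Key, Value are three learned linear projections of that
  sequence), capturing global temporal relationships; temporal mean
  pooling yields a second fixed-size vector.

The two representations are concatenated (optionally together with the
engineered 161-feature vector), passed through a dense layer and a
softmax over the activity classes. The attention scores are used as
printed — softmax(Q K^T) V without the conventional 1/sqrt(d) scaling;
``scale_attention=True`` enables the scaling as a stability escape
hatch. Training minimizes the mean cross-entropy of the class
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, conv1d
from .params import ModelParams
from .rnn import (
    cross_entropy_loss,
    glorot_uniform,
    gru_forward,
    init_gru_params,
    init_lstm_params,
    lstm_forward,
    softmax,
)

__all__ = [
    "ConvBlockSpec",
    "conv_block",
    "attention",
    "relation_network_forward",
    "PENModel",
    "cross_entropy_loss",
]


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolutional block: Conv1D -> BatchNorm -> LeakyReLU."""

    out_channels: int
    kernel_size: int = 5
    stride: int = 1
    leaky_slope: float = 0.01

    def __post_init__(self):
        if self.out_channels < 1 or self.kernel_size < 1 or self.stride < 1:
            raise ValueError("out_channels, kernel_size and stride must be >= 1")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must be in (0, 1)")


DEFAULT_CONV_SPECS = (
    ConvBlockSpec(32),
    ConvBlockSpec(64),
    ConvBlockSpec(64),
)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _leaky(x, slope: float):
    if isinstance(x, Tensor):
        return x.leaky_relu(slope)
    return np.where(x >= 0, x, slope * x)


def _batchnorm(y, gamma, beta, running_mean, running_var, mode: str):
    """Channel-wise batch normalization for [N, C, L] activations.

    Train mode uses batch statistics and updates the running estimates in
    place (outside the autodiff graph); eval mode uses running stats.
    """
    is_tensor = isinstance(y, Tensor)
    data = y.data if is_tensor else y
    n, c, length = data.shape
    if mode == "train":
        flat = y.transpose(1, 0, 2).reshape(c, n * length) if is_tensor else (
            data.transpose(1, 0, 2).reshape(c, n * length)
        )
        mean = flat.mean(axis=1, keepdims=True)
        centered = flat - mean
        var = (centered**2).mean(axis=1, keepdims=True)
        var_data = var.data if is_tensor else var
        mean_data = mean.data if is_tensor else mean
        running_mean *= 1.0 - _BN_MOMENTUM
        running_mean += _BN_MOMENTUM * mean_data.ravel()
        running_var *= 1.0 - _BN_MOMENTUM
        running_var += _BN_MOMENTUM * var_data.ravel()
        normalized = centered / (var + _BN_EPS) ** 0.5
        g = gamma.reshape(c, 1) if isinstance(gamma, Tensor) else gamma.reshape(c, 1)
        b = beta.reshape(c, 1) if isinstance(beta, Tensor) else beta.reshape(c, 1)
        out = normalized * g + b
        return out.reshape(c, n, length).transpose(1, 0, 2)
    # eval: running statistics, broadcast over [N, C, L]
    rm = running_mean.reshape(1, c, 1)
    rv = running_var.reshape(1, c, 1)
    g = gamma.reshape(1, c, 1)
    b = beta.reshape(1, c, 1)
    return (y - rm) / np.sqrt(rv + _BN_EPS) * g + b


def conv_block(x, spec: ConvBlockSpec, params, prefix: str = "", mode: str = "eval"):
    """Apply Conv1D (same padding) -> BatchNorm -> LeakyReLU to [N, C, L]."""
    shape = x.data.shape if isinstance(x, Tensor) else np.asarray(x).shape
    if shape[-1] < spec.kernel_size:
        raise ValueError(
            f"sequence length {shape[-1]} shorter than kernel {spec.kernel_size}"
        )
    y = conv1d(x, params[f"{prefix}conv.W"], params[f"{prefix}conv.b"], stride=spec.stride)
    y = _batchnorm(
        y,
        params[f"{prefix}bn.gamma"],
        params[f"{prefix}bn.beta"],
        _as_array(params[f"{prefix}bn.running_mean"]),
        _as_array(params[f"{prefix}bn.running_var"]),
        mode,
    )
    return _leaky(y, spec.leaky_slope)


def _as_array(x):
    return x.data if isinstance(x, Tensor) else x


def attention(query, key, value, scale: bool = False):
    """Dot-product attention  O = softmax(Q K^T) V.

    Accepts [L x d] matrices or batched [N x L x d] stacks, as ndarrays
    or Tensors. Rows of the softmax matrix sum to 1, so every output row
    is a convex combination of Value rows. ``scale=True`` divides the
    scores by sqrt(d) (off by default).
    """
    q_shape = query.data.shape if isinstance(query, Tensor) else np.asarray(query).shape
    k_shape = key.data.shape if isinstance(key, Tensor) else np.asarray(key).shape
    if q_shape[-1] != k_shape[-1]:
        raise ValueError(
            f"query inner dimension {q_shape[-1]} != key inner dimension {k_shape[-1]}"
        )
    batched = len(q_shape) == 3
    key_t = key.transpose(0, 2, 1) if (batched and isinstance(key, Tensor)) else (
        np.swapaxes(key, -1, -2) if batched else (key.T)
    )
    scores = ad.matmul(query, key_t)
    if scale:
        scores = scores * (1.0 / np.sqrt(q_shape[-1]))
    return ad.matmul(softmax(scores), value)


def relation_network_forward(seq, params, prefix: str = "rel.", scale: bool = False):
    """LSTM -> GRU -> self-attention -> temporal mean pooling.

    seq: [N, L, F] batch (or [L, F]); returns a fixed-length [N, d_v]
    representation independent of L.
    """
    shape = seq.data.shape if isinstance(seq, Tensor) else np.asarray(seq).shape
    if len(shape) == 2:
        seq = seq[None, :, :] if not isinstance(seq, Tensor) else seq.reshape(1, *shape)
        squeeze = True
    else:
        squeeze = False
    if (seq.data.shape if isinstance(seq, Tensor) else seq.shape)[1] == 0:
        raise ValueError("empty sequence")
    lstm_seq = lstm_forward(seq, params, prefix=f"{prefix}lstm.", return_sequence=True)
    gru_seq = gru_forward(lstm_seq, params, prefix=f"{prefix}gru.", return_sequence=True)
    # stack per-step [N, H] outputs into [N, L, H]
    steps = [
        (h.reshape(h.data.shape[0], 1, h.data.shape[1]) if isinstance(h, Tensor)
         else h[:, None, :])
        for h in gru_seq
    ]
    stacked = ad.concat(steps, axis=1)
    w_q, w_k, w_v = params[f"{prefix}W_q"], params[f"{prefix}W_k"], params[f"{prefix}W_v"]
    q = ad.matmul(stacked, w_q.T if isinstance(w_q, Tensor) else w_q.T)
    k = ad.matmul(stacked, w_k.T if isinstance(w_k, Tensor) else w_k.T)
    v = ad.matmul(stacked, w_v.T if isinstance(w_v, Tensor) else w_v.T)
    pooled = attention(q, k, v, scale=scale).mean(axis=1)
    if squeeze:
        pooled = pooled[0] if not isinstance(pooled, Tensor) else pooled.reshape(-1)
    return pooled


class PENModel:
    """Full PEN classifier over raw windowed 6-channel sequences."""

    def __init__(
        self,
        n_channels: int,
        n_classes: int,
        classes: list[str] | None = None,
        conv_specs: tuple[ConvBlockSpec, ...] = DEFAULT_CONV_SPECS,
        lstm_units: int = 32,
        gru_units: int = 16,
        attention_dim: int = 16,
        scale_attention: bool = False,
        use_engineered_features: bool = False,
        n_engineered: int = 161,
        seed: int = 0,
    ):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.classes = list(classes) if classes is not None else [
            str(c) for c in range(n_classes)
        ]
        self.conv_specs = tuple(conv_specs)
        self.lstm_units = lstm_units
        self.gru_units = gru_units
        self.attention_dim = attention_dim
        self.scale_attention = scale_attention
        self.use_engineered_features = use_engineered_features
        self.n_engineered = n_engineered
        self.seed = seed

    def init_params(self, seed: int | None = None) -> ModelParams:
        rng = np.random.default_rng(self.seed if seed is None else seed)
        tensors: dict[str, np.ndarray] = {}
        c_in = self.n_channels
        for b, spec in enumerate(self.conv_specs):
            prefix = f"feat.block{b}."
            tensors[f"{prefix}conv.W"] = glorot_uniform(
                rng, spec.out_channels, c_in * spec.kernel_size
            ).reshape(spec.out_channels, c_in, spec.kernel_size)
            tensors[f"{prefix}conv.b"] = np.zeros(spec.out_channels)
            tensors[f"{prefix}bn.gamma"] = np.ones(spec.out_channels)
            tensors[f"{prefix}bn.beta"] = np.zeros(spec.out_channels)
            tensors[f"{prefix}bn.running_mean"] = np.zeros(spec.out_channels)
            tensors[f"{prefix}bn.running_var"] = np.ones(spec.out_channels)
            c_in = spec.out_channels
        tensors.update(
            init_lstm_params(rng, self.n_channels, self.lstm_units, prefix="rel.lstm.")
        )
        tensors.update(
            init_gru_params(rng, self.lstm_units, self.gru_units, prefix="rel.gru.")
        )
        for proj in ("W_q", "W_k", "W_v"):
            tensors[f"rel.{proj}"] = glorot_uniform(
                rng, self.attention_dim, self.gru_units
            )
        head_in = self.conv_specs[-1].out_channels + self.attention_dim
        if self.use_engineered_features:
            head_in += self.n_engineered
        tensors["head.W"] = glorot_uniform(rng, self.n_classes, head_in)
        tensors["head.b"] = np.zeros(self.n_classes)
        return ModelParams(tensors)

    # running batch-norm stats are state, not trainable weights
    _NON_TRAINABLE = ("bn.running_mean", "bn.running_var")

    def is_trainable(self, name: str) -> bool:
        return not any(name.endswith(suffix) for suffix in self._NON_TRAINABLE)

    def feature_network_forward(self, x, params, mode: str = "eval"):
        """Conv blocks then temporal mean pooling: [N, C, L] -> [N, C_out]."""
        y = x
        for b, spec in enumerate(self.conv_specs):
            y = conv_block(y, spec, params, prefix=f"feat.block{b}.", mode=mode)
        return y.mean(axis=-1) if isinstance(y, Tensor) else y.mean(axis=-1)

    def forward(self, params, x, mode: str = "eval", extra_features=None):
        """Class probabilities for a batch of raw windows [N, L, C]."""
        arr_shape = x.data.shape if isinstance(x, Tensor) else np.asarray(x).shape
        if len(arr_shape) != 3 or arr_shape[2] != self.n_channels:
            raise ValueError(
                f"expected [N, L, {self.n_channels}] input, got {arr_shape}"
            )
        x_cl = x.transpose(0, 2, 1) if isinstance(x, Tensor) else np.transpose(x, (0, 2, 1))
        local = self.feature_network_forward(x_cl, params, mode=mode)
        global_rep = relation_network_forward(
            x, params, prefix="rel.", scale=self.scale_attention
        )
        parts = [local, global_rep]
        if self.use_engineered_features:
            if extra_features is None:
                raise ValueError(
                    "use_engineered_features=True requires extra_features"
                )
            parts.append(extra_features)
        merged = ad.concat(parts, axis=-1)
        w, b = params["head.W"], params["head.b"]
        logits = ad.matmul(merged, w.T if isinstance(w, Tensor) else w.T) + b
        return softmax(logits)

    def loss_and_gradients(self, params: ModelParams, x, y_one_hot, extra_features=None):
        tensors = {k: Tensor(v, requires_grad=self.is_trainable(k)) for k, v in params.items()}
        proba = self.forward(tensors, x, mode="train", extra_features=extra_features)
        loss = cross_entropy_loss(proba, y_one_hot)
        loss.backward()
        grads = {
            k: (t.grad if t.grad is not None else np.zeros_like(t.data))
            for k, t in tensors.items()
        }
        # running stats were updated in place inside _batchnorm
        updated_state = {k: tensors[k].data for k in params if not self.is_trainable(k)}
        return float(loss.data), grads, updated_state

    def sgd_step(
        self, params: ModelParams, x, y_one_hot, learning_rate: float, extra_features=None
    ) -> tuple[float, ModelParams]:
        """One full-batch gradient step; returns (loss before step, new params)."""
        loss, grads, state = self.loss_and_gradients(params, x, y_one_hot, extra_features)
        new = params.copy()
        for k in new:
            if self.is_trainable(k):
                new[k] = new[k] - learning_rate * grads[k]
            else:
                new[k] = state[k]
        return loss, new

    def one_hot(self, labels) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        out = np.zeros((len(labels), self.n_classes))
        for row, lab in enumerate(labels):
            out[row, index[lab]] = 1.0
        return out
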