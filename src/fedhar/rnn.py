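"""Reference LSTM and GRU cells and the hybrid LSTM-GRU classifier.

The cells follow the standard gate formulations over the concatenation
[q_{k-1}, y_k] of previous hidden state and current input:

LSTM:  f = sigma(U_f [q, y] + b_f)          forget gate
       i = sigma(U_i [q, y] + b_i)          input gate
       c~ = tanh(U_c [q, y] + b_c)          candidate cell state
       S' = f * S + i * c~                  cell state update
       o = sigma(U_o [q, y] + b_o)          output gate
       q' = o * tanh(S')                    hidden state

GRU:   u = sigma(U_u [q, y] + b_u)          update gate
       r = sigma(U_r [q, y] + b_r)          reset gate
       q~ = tanh(U_q [r * q, y] + b_q)      candidate activation
       q' = (1 - u) * q + u * q~            hidden state

The classifier is LSTM(128) -> GRU(64) -> dense -> softmax by default;
hidden sizes are configurable for desk-scale experiments. Training is
plain mini-batch SGD (no momentum) minimizing cross-entropy, with
optional inverse-frequency class weights and optional gradient-norm
clipping (off by default). Runs are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .params import ModelParams
from .types import ClientShard, FeatureWindow

__all__ = [
    "LSTMState",
    "TrainConfig",
    "TrainingError",
    "lstm_step",
    "gru_step",
    "build_classifier",
    "HybridClassifier",
    "train_local",
    "cross_entropy_loss",
    "glorot_uniform",
]


class TrainingError(RuntimeError):
    pass


@dataclass
class LSTMState:
    """Hidden state q_k and cell state S_k of an LSTM cell."""

    hidden: object  # ndarray or Tensor, [..., H]
    cell: object

    @classmethod
    def zeros(cls, hidden_size: int, batch: int | None = None) -> "LSTMState":
        shape = (hidden_size,) if batch is None else (batch, hidden_size)
        return cls(hidden=np.zeros(shape), cell=np.zeros(shape))


@dataclass(frozen=True)
class TrainConfig:
    """Local-training protocol: SGD, lr 0.001, batch 32, 30 local epochs."""

    learning_rate: float = 0.001
    batch_size: int = 32
    local_epochs: int = 30
    seed: int = 0
    grad_clip: float | None = None  # max gradient norm; None disables
    class_weights: dict[str, float] | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.local_epochs < 0:
            raise ValueError("local_epochs must be >= 0")


def _affine(z, weight, bias):
    """z @ weight.T + bias for ndarray or Tensor operands."""
    return ad.matmul(z, weight.T if isinstance(weight, Tensor) else weight.T) + bias


def lstm_step(state: LSTMState, y_k, p) -> LSTMState:
    """One LSTM time step. ``p`` maps U_f/U_i/U_c/U_o and b_* tensors."""
    z = ad.concat([state.hidden, y_k], axis=-1)
    f = ad.sigmoid(_affine(z, p["U_f"], p["b_f"]))
    i = ad.sigmoid(_affine(z, p["U_i"], p["b_i"]))
    c_tilde = ad.tanh(_affine(z, p["U_c"], p["b_c"]))
    cell = f * state.cell + i * c_tilde
    o = ad.sigmoid(_affine(z, p["U_o"], p["b_o"]))
    hidden = o * ad.tanh(cell)
    return LSTMState(hidden=hidden, cell=cell)


def gru_step(q_prev, y_k, p):
    """One GRU time step. ``p`` maps U_u/U_r/U_q and b_u/b_r/b_q tensors."""
    z = ad.concat([q_prev, y_k], axis=-1)
    u = ad.sigmoid(_affine(z, p["U_u"], p["b_u"]))
    r = ad.sigmoid(_affine(z, p["U_r"], p["b_r"]))
    z_reset = ad.concat([r * q_prev, y_k], axis=-1)
    q_tilde = ad.tanh(_affine(z_reset, p["U_q"], p["b_q"]))
    return (1.0 - u) * q_prev + u * q_tilde


def glorot_uniform(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def init_lstm_params(
    rng: np.random.Generator, input_size: int, hidden_size: int, prefix: str = ""
) -> dict[str, np.ndarray]:
    fan_in = hidden_size + input_size
    out = {}
    for gate in ("f", "i", "c", "o"):
        out[f"{prefix}U_{gate}"] = glorot_uniform(rng, hidden_size, fan_in)
        out[f"{prefix}b_{gate}"] = np.zeros(hidden_size)
    return out


def init_gru_params(
    rng: np.random.Generator, input_size: int, hidden_size: int, prefix: str = ""
) -> dict[str, np.ndarray]:
    fan_in = hidden_size + input_size
    out = {}
    for gate in ("u", "r", "q"):
        out[f"{prefix}U_{gate}"] = glorot_uniform(rng, hidden_size, fan_in)
        out[f"{prefix}b_{gate}"] = np.zeros(hidden_size)
    return out


def lstm_forward(x_seq, p, prefix: str = "", return_sequence: bool = False):
    """Run an LSTM over [N, L, F] (or [L, F]) input; zero initial state."""
    batched = (x_seq.ndim if not isinstance(x_seq, Tensor) else x_seq.data.ndim) == 3
    shape = x_seq.shape if not isinstance(x_seq, Tensor) else x_seq.data.shape
    hidden_size = p[f"{prefix}b_f"].shape[-1]
    state = LSTMState.zeros(hidden_size, batch=shape[0] if batched else None)
    local = {k[len(prefix):]: v for k, v in p.items() if k.startswith(prefix)}
    outputs = []
    steps = shape[1] if batched else shape[0]
    for k in range(steps):
        y_k = x_seq[:, k, :] if batched else x_seq[k]
        state = lstm_step(state, y_k, local)
        if return_sequence:
            outputs.append(state.hidden)
    if return_sequence:
        return outputs
    return state.hidden


def gru_forward(x_steps: list, p, prefix: str = "", return_sequence: bool = False):
    """Run a GRU over a list of per-step inputs; zero initial state."""
    hidden_size = p[f"{prefix}b_u"].shape[-1]
    first = x_steps[0]
    shape = first.shape if not isinstance(first, Tensor) else first.data.shape
    batch = shape[0] if len(shape) == 2 else None
    q = np.zeros((batch, hidden_size)) if batch is not None else np.zeros(hidden_size)
    local = {k[len(prefix):]: v for k, v in p.items() if k.startswith(prefix)}
    outputs = []
    for y_k in x_steps:
        q = gru_step(q, y_k, local)
        if return_sequence:
            outputs.append(q)
    return outputs if return_sequence else q


def cross_entropy_loss(predictions, targets_one_hot, sample_weights=None):
    """Mean cross-entropy  L = -(1/N) sum_i w_i t_i . log p_i.

    predictions: probability rows [N x C] (ndarray or Tensor), clamped at
    1e-12 before the log; targets_one_hot: [N x C]. Optional per-sample
    weights scale each sample's contribution (and hence its gradient).
    """
    t = np.asarray(targets_one_hot, dtype=np.float64)
    if isinstance(predictions, Tensor):
        n = predictions.data.shape[0]
        if predictions.data.shape != t.shape:
            raise ValueError("predictions and targets shapes differ")
        logp = predictions.clip_min(1e-12).log()
        per_sample = -(logp * t).sum(axis=1)
        if sample_weights is not None:
            per_sample = per_sample * np.asarray(sample_weights, dtype=np.float64)
        return per_sample.sum() / float(n)
    p = np.asarray(predictions, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("predictions and targets shapes differ")
    per_sample = -(t * np.log(np.maximum(p, 1e-12))).sum(axis=1)
    if sample_weights is not None:
        per_sample = per_sample * np.asarray(sample_weights, dtype=np.float64)
    return float(per_sample.mean())


def softmax(logits):
    if isinstance(logits, Tensor):
        shifted = logits - logits.data.max(axis=-1, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=-1, keepdims=True)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class HybridClassifier:
    """LSTM -> GRU -> dense -> softmax sequence classifier.

    ``input_mode`` selects the design matrix: "features" feeds each
    window's scaled 161-vector as a length-1 sequence; "sequence" feeds
    the raw [L x 6] samples.
    """

    def __init__(
        self,
        n_features: int,
        n_classes: int,
        classes: list[str] | None = None,
        lstm_units: int = 128,
        gru_units: int = 64,
        input_mode: str = "features",
        seed: int = 0,
    ):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if input_mode not in ("features", "sequence"):
            raise ValueError("input_mode must be 'features' or 'sequence'")
        self.n_features = n_features
        self.n_classes = n_classes
        self.classes = list(classes) if classes is not None else [
            str(c) for c in range(n_classes)
        ]
        if len(self.classes) != n_classes:
            raise ValueError("classes list does not match n_classes")
        self.hidden_sizes = (lstm_units, gru_units)
        self.input_mode = input_mode
        self.seed = seed

    # -- parameters -------------------------------------------------------

    def init_params(self, seed: int | None = None) -> ModelParams:
        rng = np.random.default_rng(self.seed if seed is None else seed)
        h1, h2 = self.hidden_sizes
        tensors = {}
        tensors.update(init_lstm_params(rng, self.n_features, h1, prefix="lstm."))
        tensors.update(init_gru_params(rng, h1, h2, prefix="gru."))
        tensors["dense.W"] = glorot_uniform(rng, self.n_classes, h2)
        tensors["dense.b"] = np.zeros(self.n_classes)
        return ModelParams(tensors)

    @property
    def parameter_count(self) -> int:
        """Closed-form count: 4 h1 (h1+F+1) + 3 h2 (h2+h1+1) + C (h2+1)."""
        h1, h2 = self.hidden_sizes
        return (
            4 * h1 * (h1 + self.n_features + 1)
            + 3 * h2 * (h2 + h1 + 1)
            + self.n_classes * (h2 + 1)
        )

    # -- data plumbing ----------------------------------------------------

    def design_matrix(self, windows: list[FeatureWindow]) -> np.ndarray:
        """Stack windows into a [N, L, F] sequence batch."""
        if self.input_mode == "features":
            rows = []
            for w in windows:
                if w.features is None:
                    raise TrainingError(
                        f"window {w.window_id} has no feature vector attached"
                    )
                rows.append(w.features)
            return np.asarray(rows, dtype=np.float64)[:, None, :]
        return np.stack([np.asarray(w.sequence, dtype=np.float64) for w in windows])

    def one_hot(self, labels) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        out = np.zeros((len(labels), self.n_classes))
        for row, lab in enumerate(labels):
            if lab not in index:
                raise TrainingError(f"unknown class label {lab!r}")
            out[row, index[lab]] = 1.0
        return out

    # -- forward ----------------------------------------------------------

    def forward(self, params, x):
        """Class probabilities [N x C] for a batch [N, L, F].

        Works on plain ndarrays (inference) and on parameter Tensors
        (training, differentiable).
        """
        lstm_seq = lstm_forward(x, params, prefix="lstm.", return_sequence=True)
        q = gru_forward(lstm_seq, params, prefix="gru.")
        logits = _affine(q, params["dense.W"], params["dense.b"])
        return softmax(logits)

    def predict_proba(self, params: ModelParams, windows: list[FeatureWindow]):
        return self.forward(dict(params.items()), self.design_matrix(windows))

    def predict(self, params: ModelParams, windows: list[FeatureWindow]) -> list[str]:
        proba = self.predict_proba(params, windows)
        return [self.classes[i] for i in np.argmax(proba, axis=1)]

    # -- training ---------------------------------------------------------

    def loss_and_gradients(self, params: ModelParams, x, y_one_hot, sample_weights=None):
        tensors = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
        proba = self.forward(tensors, x)
        loss = cross_entropy_loss(proba, y_one_hot, sample_weights)
        loss.backward()
        grads = {
            k: (t.grad if t.grad is not None else np.zeros_like(t.data))
            for k, t in tensors.items()
        }
        return float(loss.data), grads

    def train_local(
        self, params: ModelParams, shard: ClientShard, config: TrainConfig
    ) -> ModelParams:
        """``config.local_epochs`` passes of seeded mini-batch SGD.

        Returns updated parameters without mutating the input.
        """
        if shard.size == 0:
            raise TrainingError(f"client {shard.client_id} has an empty shard")
        x = self.design_matrix(shard.windows)
        y = self.one_hot(shard.labels)
        weights = None
        if config.class_weights is not None:
            weights = np.array(
                [config.class_weights.get(lab, 1.0) for lab in shard.labels]
            )
        rng = np.random.default_rng(config.seed)
        current = params.copy()
        n = x.shape[0]
        for _ in range(config.local_epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = order[start : start + config.batch_size]
                _, grads = self.loss_and_gradients(
                    current,
                    x[batch],
                    y[batch],
                    None if weights is None else weights[batch],
                )
                if config.grad_clip is not None:
                    norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
                    if norm > config.grad_clip:
                        scale = config.grad_clip / norm
                        grads = {k: g * scale for k, g in grads.items()}
                for k in current:
                    current[k] = current[k] - config.learning_rate * grads[k]
        return current

    def evaluate_loss(self, params: ModelParams, windows: list[FeatureWindow]) -> float:
        proba = self.predict_proba(params, windows)
        return cross_entropy_loss(proba, self.one_hot([w.label for w in windows]))


def build_classifier(
    n_features: int,
    n_classes: int,
    config: dict | None = None,
    classes: list[str] | None = None,
) -> HybridClassifier:
    """Construct the LSTM(128) -> GRU(64) classifier (sizes overridable)."""
    cfg = dict(config or {})
    return HybridClassifier(
        n_features=n_features,
        n_classes=n_classes,
        classes=classes,
        lstm_units=int(cfg.get("lstm_units", 128)),
        gru_units=int(cfg.get("gru_units", 64)),
        input_mode=cfg.get("input_mode", "features"),
        seed=int(cfg.get("seed", 0)),
    )


def train_local(
    model: HybridClassifier,
    params: ModelParams,
    shard: ClientShard,
    config: TrainConfig,
) -> ModelParams:
    """Functional alias for HybridClassifier.train_local."""
    return model.train_local(params, shard, config)


def with_seed(config: TrainConfig, seed: int) -> TrainConfig:
    return replace(config, seed=seed)
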