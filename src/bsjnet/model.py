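"""The junction classifier: conv stack -> self-attention -> adaptive max
pool -> fully connected head -> softmax, trained with cross-entropy.

The architecture mirrors the common design for splice-site sequence
classification: a three-layer 1-D convolution module (each layer followed by
a normalization layer and LeakyReLU) captures local motif patterns around
the two back-splice sites; a single scaled dot-product self-attention layer
models interactions between positions; global adaptive max pooling keeps the
most salient activation per channel; and a fully connected layer maps the
pooled vector to the two class logits.

``JunctionClassifier`` wraps the whole thing as a scikit-learn estimator
(fit / predict / predict_proba / get_params) over pre-computed embedding
tensors of shape (n_examples, positions, dim).  The module-level functions
(`self_attention`, `adaptive_max_pool`, `fc_forward`, `softmax_probs`,
`cross_entropy`) expose the individual stages for inspection and testing.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from ._nn import (
    Adam,
    AdaptiveMaxPool,
    BatchNorm1d,
    Conv1dSame,
    Dropout,
    LayerNorm,
    LeakyReLU,
    Linear,
    MultiHeadSelfAttention,
    SGD,
    Sequential,
    softmax_cross_entropy,
    stable_softmax,
)

DEFAULT_LEARNING_RATE = 0.005  # ablation optimum for this architecture


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    conv_channels: output width of each of the convolutional layers.
    kernel_size: odd convolution width (symmetric same-padding).
    leaky_slope: negative slope of the LeakyReLU activations.
    norm: "batch" (default), "layer", or None.
    attention_heads: number of self-attention heads; must divide the
        attention width (the last conv channel count).
    use_attention: ablation toggle for the self-attention layer.
    linear_layers: depth of the fully connected head (1 is the default;
        deeper heads interleave LeakyReLU between linear maps).
    num_classes: fixed at 2 (circRNA vs lncRNA).
    """

    conv_channels: tuple[int, ...] = (256, 128, 64)
    kernel_size: int = 3
    leaky_slope: float = 0.01
    norm: str | None = "batch"
    attention_heads: int = 4
    use_attention: bool = True
    linear_layers: int = 1
    fc_hidden: int = 32
    dropout: float = 0.0
    num_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_channels) < 1:
            raise ValueError("need at least one convolutional layer")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        width = self.conv_channels[-1]
        if self.use_attention and width % self.attention_heads != 0:
            raise ValueError(
                f"attention_heads={self.attention_heads} must divide conv width {width}"
            )
        if self.num_classes != 2:
            raise ValueError("this classifier is strictly binary")
        if self.linear_layers < 1:
            raise ValueError("need at least one linear layer")


def build_network(config: ModelConfig, input_dim: int, rng: np.random.Generator) -> Sequential:
    """Assemble the full stack with seeded parameter initialization."""
    layers: list[_nn.Layer] = []
    in_ch = input_dim
    for out_ch in config.conv_channels:
        layers.append(Conv1dSame(in_ch, out_ch, config.kernel_size, rng))
        if config.norm == "batch":
            layers.append(BatchNorm1d(out_ch))
        elif config.norm == "layer":
            layers.append(LayerNorm(out_ch))
        elif config.norm is not None:
            raise ValueError(f"unknown norm {config.norm!r}")
        layers.append(LeakyReLU(config.leaky_slope))
        in_ch = out_ch
    if config.use_attention:
        layers.append(MultiHeadSelfAttention(in_ch, config.attention_heads, rng))
    layers.append(AdaptiveMaxPool())
    if config.dropout > 0:
        layers.append(Dropout(config.dropout, rng))
    width = in_ch
    for i in range(config.linear_layers - 1):
        layers.append(Linear(width, config.fc_hidden, rng))
        layers.append(LeakyReLU(config.leaky_slope))
        width = config.fc_hidden
    layers.append(Linear(width, config.num_classes, rng))
    return Sequential(layers)


# ---------------------------------------------------------------------------
# Functional stage-by-stage surface (used directly in tests and notebooks)
# ---------------------------------------------------------------------------


def conv_forward(x: np.ndarray, config: ModelConfig, rng=None, network: Sequential | None = None):
    """Run only the convolution module (conv/norm/activation blocks).

    ``x`` is (positions, dim) or (batch, positions, dim).  A pre-built
    network can be passed to reuse trained parameters; otherwise a fresh
    seeded one is initialized.
    """
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    if network is None:
        network = build_network(config, xb.shape[-1], rng or np.random.default_rng(0))
    n_blocks = len(config.conv_channels) * (2 + (config.norm is not None))
    out = Sequential(network.layers[:n_blocks]).forward(xb, train=False)
    return out[0] if squeeze else out


def self_attention(
    x_cnn: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    w_v: np.ndarray,
    heads: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product self-attention over positions.

    Q = X W_Q, K = X W_K, V = X W_V; per head the attention matrix is the
    row-wise softmax of Q K^T / sqrt(D_k) (D_k = per-head key width), and
    the output is attention @ V with heads concatenated.  Returns
    (X_att, attention_weights); the weight rows each sum to 1.
    """
    squeeze = x_cnn.ndim == 2
    xb = x_cnn[None] if squeeze else x_cnn
    width = xb.shape[-1]
    layer = MultiHeadSelfAttention(width, heads, np.random.default_rng(0))
    layer.params["W_Q"], layer.params["W_K"], layer.params["W_V"] = w_q, w_k, w_v
    out = layer.forward(xb, train=False)
    weights = layer.last_attention
    if heads == 1:
        weights = weights[:, 0]
    if squeeze:
        return out[0], weights[0]
    return out, weights


def adaptive_max_pool(x_att: np.ndarray) -> np.ndarray:
    """Global max over positions: Y_j = max_i X[i, j] (output size 1)."""
    x_att = np.asarray(x_att, dtype=np.float64)
    if x_att.size == 0:
        raise ValueError("cannot pool an empty matrix")
    return x_att.max(axis=-2)


def fc_forward(y: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Linear decision map z = W . Y^T + b."""
    return np.asarray(y) @ np.asarray(w).T + np.asarray(b)


def softmax_probs(z: np.ndarray) -> np.ndarray:
    """Class probabilities from logits, computed with max-subtraction."""
    return stable_softmax(z, axis=-1)


def cross_entropy(probs: np.ndarray, y: int | np.ndarray) -> float:
    """Cross-entropy -sum_i y_i log(p_i) with one-hot targets, i.e.
    -log p_true per example; batched inputs return the mean.  Probabilities
    are clamped at 1e-12 before the log."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    y_arr = np.atleast_1d(np.asarray(y, dtype=int))
    p_true = probs[np.arange(len(y_arr)), y_arr]
    return float(-np.log(np.clip(p_true, _nn.LOG_EPS, None)).mean())


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class JunctionClassifier(BaseEstimator, ClassifierMixin):
    """Binary circRNA-vs-lncRNA classifier over junction embeddings.

    Parameters mirror :class:`ModelConfig` plus the training loop knobs.
    ``fit`` expects ``X`` of shape (n_examples, positions, dim) — e.g. the
    output of an embedder's ``transform`` — and binary ``y`` (1 = circRNA).

    Attributes set by fit: ``network_`` (trained layers), ``history_``
    (per-epoch train/validation loss), ``classes_``, ``input_dim_``.
    """

    def __init__(
        self,
        conv_channels: tuple[int, ...] = (256, 128, 64),
        kernel_size: int = 3,
        leaky_slope: float = 0.01,
        norm: str | None = "batch",
        attention_heads: int = 4,
        use_attention: bool = True,
        linear_layers: int = 1,
        fc_hidden: int = 32,
        dropout: float = 0.0,
        learning_rate: float = DEFAULT_LEARNING_RATE,
        epochs: int = 30,
        batch_size: int = 64,
        optimizer: str = "adam",
        early_stop_patience: int = 5,
        class_weight: str | None = None,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.leaky_slope = leaky_slope
        self.norm = norm
        self.attention_heads = attention_heads
        self.use_attention = use_attention
        self.linear_layers = linear_layers
        self.fc_hidden = fc_hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.early_stop_patience = early_stop_patience
        self.class_weight = class_weight
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ----------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            conv_channels=tuple(self.conv_channels),
            kernel_size=self.kernel_size,
            leaky_slope=self.leaky_slope,
            norm=self.norm,
            attention_heads=self.attention_heads,
            use_attention=self.use_attention,
            linear_layers=self.linear_layers,
            fc_hidden=self.fc_hidden,
            dropout=self.dropout,
        )

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_examples, positions, dim), got shape {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def _mean_loss(self, X: np.ndarray, y: np.ndarray, weights: np.ndarray | None) -> float:
        logits = self._forward_batched(X, train=False)
        probs = stable_softmax(logits, axis=-1)
        ll = -np.log(np.clip(probs[np.arange(len(y)), y], _nn.LOG_EPS, None))
        if weights is None:
            return float(ll.mean())
        w = weights[y]
        return float((ll * w).sum() / w.sum())

    def _forward_batched(self, X: np.ndarray, train: bool) -> np.ndarray:
        outs = [
            self.network_.forward(X[i : i + self.batch_size], train=train)
            for i in range(0, len(X), self.batch_size)
        ]
        return np.concatenate(outs) if outs else np.empty((0, 2))

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary in {0, 1}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        config = self._model_config()
        rng = np.random.default_rng(self.random_state)
        self.input_dim_ = X.shape[-1]
        self.n_positions_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.network_ = build_network(config, self.input_dim_, rng)

        if self.class_weight == "balanced":
            counts = np.bincount(y, minlength=2).astype(float)
            cls_w = len(y) / (2.0 * np.maximum(counts, 1))
        elif self.class_weight is None:
            cls_w = None
        else:
            raise ValueError(f"unknown class_weight {self.class_weight!r}")

        named = list(self.network_.named_params())
        if self.optimizer == "adam":
            opt = Adam(named, self.learning_rate)
        elif self.optimizer == "sgd":
            opt = SGD(named, self.learning_rate)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        val = None
        if validation_data is not None:
            Xv, yv = validation_data
            val = (self._check_X(Xv), np.asarray(yv, dtype=int))

        history = {"epoch": [], "train_loss": [], "val_loss": []}
        best_val = np.inf
        best_state = None
        patience_left = self.early_stop_patience
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                logits = self.network_.forward(X[idx], train=True)
                if cls_w is None:
                    loss, dlogits = softmax_cross_entropy(logits, y[idx])
                else:
                    probs = stable_softmax(logits, axis=-1)
                    w = cls_w[y[idx]]
                    ll = -np.log(np.clip(probs[np.arange(len(idx)), y[idx]], _nn.LOG_EPS, None))
                    loss = float((ll * w).sum() / w.sum())
                    dlogits = probs.copy()
                    dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                    dlogits *= (w / w.sum())[:, None]
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: loss={loss} at epoch {epoch}, "
                        f"lr={self.learning_rate}; try a lower learning rate"
                    )
                self.network_.backward(dlogits)
                opt.step()
                epoch_loss += loss * len(idx)
            train_loss = epoch_loss / n
            val_loss = self._mean_loss(*val, None) if val is not None else np.nan
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if self.verbose:
                print(f"epoch {epoch}: train_loss={train_loss:.4f} val_loss={val_loss:.4f}")
            if val is not None:
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_state = copy.deepcopy(
                        [layer.params for layer in self.network_.layers]
                    )
                    patience_left = self.early_stop_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_state is not None:
            for layer, params in zip(self.network_.layers, best_state):
                layer.params = params
        self.history_ = history
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._check_X(X)
        logits = self._forward_batched(X, train=False)
        return logits[:, 1] - logits[:, 0]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._check_X(X)
        if len(X) == 0:
            return np.empty((0, 2))
        return stable_softmax(self._forward_batched(X, train=False), axis=-1)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- checkpointing ----------------------------------------------------

    def save(self, path, embedder_id: str = "") -> None:
        """Single self-describing checkpoint (config + tensors + provenance)."""
        check_is_fitted(self, "network_")
        arrays: dict[str, np.ndarray] = {}
        extras: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.network_.layers):
            for key, val in layer.params.items():
                arrays[f"layer{i}.{key}"] = val
            if isinstance(layer, BatchNorm1d):
                extras[f"layer{i}.running_mean"] = layer.running_mean
                extras[f"layer{i}.running_var"] = layer.running_var
        meta = {
            "params": self.get_params(),
            "embedder_id": embedder_id,
            "input_dim": int(self.input_dim_),
            "n_positions": int(self.n_positions_),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays, **extras)

    @classmethod
    def load(cls, path) -> tuple["JunctionClassifier", str]:
        """Restore (estimator, embedder_id) from a checkpoint."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            est = cls(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in meta["params"].items()})
            est.input_dim_ = meta["input_dim"]
            est.n_positions_ = meta["n_positions"]
            est.classes_ = np.array([0, 1])
            est.network_ = build_network(
                est._model_config(), est.input_dim_, np.random.default_rng(est.random_state)
            )
            for i, layer in enumerate(est.network_.layers):
                for key in layer.params:
                    layer.params[key] = data[f"layer{i}.{key}"]
                if isinstance(layer, BatchNorm1d):
                    layer.running_mean = data[f"layer{i}.running_mean"]
                    layer.running_var = data[f"layer{i}.running_var"]
            est.history_ = {}
        return est, meta["embedder_id"]
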