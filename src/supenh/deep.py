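"""Deep classifier over the fused tri-segment embedding features.

The 576-dimensional deep feature vector is viewed as a sequence of 9
tokens of width 64 — one token per (k, segment) block in the order
(k=4: up, mid, down), (k=5: ...), (k=6: ...) — so attention, convolution
and recurrence have a sequence axis to operate on.  The network is

    multi-head self-attention (residual)
    -> 1-D convolution blocks (ReLU, same padding)
    -> max pooling
    -> GRU (last hidden state)
    -> dropout -> dense (ReLU) -> dense(1) -> sigmoid

trained with Adam on binary cross-entropy, early-stopping on validation
loss.  The implementation is a compact float64 numpy network on the
package's reverse-mode autodiff core; training is single-threaded and
reproducible under a fixed seed.  Inputs are standardized per column with
statistics fitted on the training split.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from supenh._autodiff import Tensor, concat, parameter, zeros
from supenh.models import TrainedModel

logger = logging.getLogger(__name__)


class ConstructionError(ValueError):
    """Inconsistent architecture configuration or input shape."""


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class DeepModelConfig:
    """Architecture and optimization settings for the deep classifier.

    Defaults are modest-capacity choices for 576-d inputs on small
    datasets; all are configurable.
    """

    attention_heads: int = 4
    conv_blocks: tuple[tuple[int, int], ...] = ((64, 3), (64, 5))  # (filters, kernel)
    pool: int = 2
    gru_units: int = 64
    dropout: float = 0.3
    dense_units: int = 64
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attention_heads < 1 or self.gru_units < 1 or self.dense_units < 1:
            raise ConstructionError("all layer sizes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConstructionError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.pool < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ConstructionError("pool, epochs and batch_size must be >= 1")
        for filters, kernel in self.conv_blocks:
            if filters < 1 or kernel < 1 or kernel % 2 == 0:
                raise ConstructionError(
                    f"conv blocks need filters >= 1 and odd kernel size, got {(filters, kernel)}"
                )


class DeepSequenceClassifier:
    """Attention/conv/GRU network over (n_tokens, token_dim) feature blocks."""

    def __init__(self, config: DeepModelConfig, n_features: int, token_dim: int = 64):
        if n_features % token_dim != 0:
            raise ConstructionError(
                f"feature length {n_features} is not a multiple of token width {token_dim}"
            )
        if token_dim % config.attention_heads != 0:
            raise ConstructionError(
                f"attention_heads={config.attention_heads} must divide token width {token_dim}"
            )
        self.config = config
        self.n_features = n_features
        self.token_dim = token_dim
        self.n_tokens = n_features // token_dim
        self.scaler_mean_: np.ndarray | None = None
        self.scaler_std_: np.ndarray | None = None
        self._init_params(np.random.default_rng(config.seed))
        n_params = sum(p.data.size for p in self.params.values())
        logger.info("deep model built: %d tokens x %d dims, %d parameters", self.n_tokens, token_dim, n_params)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg, d = self.config, self.token_dim
        p: dict[str, Tensor] = {}
        for name in ("wq", "wk", "wv", "wo"):
            p[name] = parameter(rng, d, d)
            p[name + "_b"] = zeros(d)
        c_in = d
        for i, (filters, kernel) in enumerate(cfg.conv_blocks):
            p[f"conv{i}_w"] = parameter(rng, kernel, c_in, filters)
            p[f"conv{i}_b"] = zeros(filters)
            c_in = filters
        u = cfg.gru_units
        for gate in ("z", "r", "n"):
            p[f"gru_w{gate}"] = parameter(rng, c_in, u)
            p[f"gru_u{gate}"] = parameter(rng, u, u)
            p[f"gru_b{gate}"] = zeros(u)
        p["dense_w"] = parameter(rng, u, cfg.dense_units)
        p["dense_b"] = zeros(cfg.dense_units)
        p["out_w"] = parameter(rng, cfg.dense_units, 1)
        p["out_b"] = zeros(1)
        self.params = p

    # -- forward --------------------------------------------------------
    def _attention(self, x: Tensor, batch: int) -> Tensor:
        cfg, d, t = self.config, self.token_dim, self.n_tokens
        h, dh = cfg.attention_heads, d // cfg.attention_heads
        p = self.params

        def split_heads(m: Tensor) -> Tensor:
            return m.reshape(batch, t, h, dh).transpose((0, 2, 1, 3))

        q = split_heads(x @ p["wq"] + p["wq_b"])
        k = split_heads(x @ p["wk"] + p["wk_b"])
        v = split_heads(x @ p["wv"] + p["wv_b"])
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        attended = scores.softmax(axis=-1) @ v  # (B, H, T, dh)
        merged = attended.transpose((0, 2, 1, 3)).reshape(batch, t, d)
        return x + (merged @ p["wo"] + p["wo_b"])  # residual connection

    def _conv_blocks(self, x: Tensor, batch: int) -> Tensor:
        t = self.n_tokens
        for i, (filters, kernel) in enumerate(self.config.conv_blocks):
            w, b = self.params[f"conv{i}_w"], self.params[f"conv{i}_b"]
            half = (kernel - 1) // 2
            pad = Tensor(np.zeros((batch, half, x.shape[-1])))
            padded = concat([pad, x, pad], axis=1)
            terms = [padded[:, j : j + t, :] @ w[j] for j in range(kernel)]
            acc = terms[0]
            for term in terms[1:]:
                acc = acc + term
            x = (acc + b).relu()
        return x

    def _gru(self, x: Tensor, batch: int, steps: int) -> Tensor:
        p = self.params
        h = Tensor(np.zeros((batch, self.config.gru_units)))
        for step in range(steps):
            xt = x[:, step, :]
            z = (xt @ p["gru_wz"] + h @ p["gru_uz"] + p["gru_bz"]).sigmoid()
            r = (xt @ p["gru_wr"] + h @ p["gru_ur"] + p["gru_br"]).sigmoid()
            n = (xt @ p["gru_wn"] + (r * h) @ p["gru_un"] + p["gru_bn"]).tanh()
            h = z * h + (1.0 - z) * n
        return h

    def forward(self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """Class-1 probabilities, shape (batch, 1), values in [0, 1]."""
        batch = X.shape[0]
        x = Tensor(X).reshape(batch, self.n_tokens, self.token_dim)
        x = self._attention(x, batch)
        x = self._conv_blocks(x, batch)
        pool = self.config.pool
        if pool > 1 and x.shape[1] >= pool:
            pooled_t = x.shape[1] // pool
            x = x[:, : pooled_t * pool, :].reshape(batch, pooled_t, pool, x.shape[-1]).max(axis=2)
        h = self._gru(x, batch, x.shape[1])
        if train and self.config.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            keep = 1.0 - self.config.dropout
            mask = (rng.random(h.shape) < keep) / keep
            h = h * Tensor(mask)
        h = (h @ self.params["dense_w"] + self.params["dense_b"]).relu()
        return (h @ self.params["out_w"] + self.params["out_b"]).sigmoid()

    # -- training -------------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean_) / self.scaler_std_

    @staticmethod
    def _bce(p: Tensor, y: np.ndarray) -> Tensor:
        eps = 1e-9
        yt = Tensor(y.reshape(-1, 1))
        return -(yt * (p + eps).log() + (1.0 - yt) * (1.0 - p + eps).log()).mean()

    def fit(self, X_train, y_train, X_val, y_val) -> "DeepSequenceClassifier":
        cfg = self.config
        X_train = np.asarray(X_train, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y_train = np.asarray(y_train, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if len(X_train) < 50:
            logger.warning(
                "only %d training samples: the deep model will very likely overfit", len(X_train)
            )
        self.scaler_mean_ = X_train.mean(axis=0)
        std = X_train.std(axis=0)
        self.scaler_std_ = np.where(std > 0, std, 1.0)
        Xtr, Xva = self._standardize(X_train), self._standardize(X_val)

        rng = np.random.default_rng(cfg.seed + 1)
        adam_m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        adam_v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, best_params, patience_left = np.inf, None, cfg.patience
        n = len(Xtr)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                proba = self.forward(Xtr[sel], train=True, rng=rng)
                loss = self._bce(proba, y_train[sel])
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, step {step}"
                    )
                for p in self.params.values():
                    p.grad = None
                loss.backward()
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for k, p in self.params.items():
                    g = p.grad if p.grad is not None else np.zeros_like(p.data)
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                    p.data -= lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)
            val_loss = float(self._bce(self.forward(Xva), y_val).data)
            if not np.isfinite(val_loss):
                raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = {k: p.data.copy() for k, p in self.params.items()}
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stopping at epoch %d (best val loss %.4f)", epoch, best_loss)
                    break
        if best_params is not None:
            for k, p in self.params.items():
                p.data = best_params[k]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Flat class-1 probability vector (inference mode, no dropout)."""
        X = np.asarray(X, dtype=float)
        if self.scaler_mean_ is not None:
            X = self._standardize(X)
        return self.forward(X).data.ravel()

    # -- persistence (Tensors hold closures, so pickle plain arrays) ----
    def __getstate__(self):
        return {
            "config": self.config,
            "n_features": self.n_features,
            "token_dim": self.token_dim,
            "scaler_mean_": self.scaler_mean_,
            "scaler_std_": self.scaler_std_,
            "param_data": {k: p.data for k, p in self.params.items()},
        }

    def __setstate__(self, state):
        self.config = state["config"]
        self.n_features = state["n_features"]
        self.token_dim = state["token_dim"]
        self.n_tokens = self.n_features // self.token_dim
        self.scaler_mean_ = state["scaler_mean_"]
        self.scaler_std_ = state["scaler_std_"]
        self._init_params(np.random.default_rng(self.config.seed))
        for k, p in self.params.items():
            p.data = state["param_data"][k]


def build_deep_model(
    config: DeepModelConfig, n_features: int, token_dim: int = 64
) -> DeepSequenceClassifier:
    """Construct the untrained deep classifier for a given feature layout."""
    return DeepSequenceClassifier(config, n_features, token_dim)


def train_deep_model(
    model: DeepSequenceClassifier, X_train, y_train, X_val, y_val
) -> TrainedModel:
    """Fit and wrap the deep model as an ensemble member (space "deep")."""
    if isinstance(X_train, pd.DataFrame):
        names = tuple(map(str, X_train.columns))
        X_train = X_train.to_numpy(dtype=float)
    else:
        names = tuple(f"f{i}" for i in range(np.asarray(X_train).shape[1]))
    if isinstance(X_val, pd.DataFrame):
        X_val = X_val.to_numpy(dtype=float)
    model.fit(X_train, y_train, X_val, y_val)
    return TrainedModel(
        kind="deep",
        space="deep",
        feature_names=names,
        estimator=model,
        metadata={"config": model.config, "seed": model.config.seed},
    )
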