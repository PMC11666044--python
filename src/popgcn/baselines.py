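"""Baseline classifiers: numpy MLPs and scikit-learn SVM-RBF / random forest.

The MLP is trained exactly like the GCN (full-batch Adam, weight decay,
early stopping on validation loss, masked cross-entropy); with one hidden
layer, no biases, and an identity adjacency it is numerically identical to
the two-layer GCN, which the test suite exploits as a cross-model oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Dense, Dropout, Module, Tensor, TrainState, fit_early_stopping
from .nn.autodiff import log_softmax, softplus, take_pairs

__all__ = ["MLPConfig", "MLPModel", "train_mlp", "predict_mlp"]


@dataclass
class MLPConfig:
    hidden_units: int = 64
    n_hidden_layers: int = 1
    learning_rate: float = 1e-3
    dropout: float = 0.2
    weight_decay: float = 1e-5
    max_epochs: int = 500
    patience: int = 20
    n_classes: int = 3
    seed: int = 0
    bias: bool = True

    def __post_init__(self):
        if self.n_hidden_layers < 1:
            raise ValueError("n_hidden_layers must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


class MLPModel(Module):
    """Dropout on every layer input; ReLU on hidden layers; linear head."""

    def __init__(self, input_dim: int, config: MLPConfig):
        rng = np.random.default_rng(config.seed)
        out_dim = 1 if config.n_classes == 2 else config.n_classes
        dims = [input_dim] + [config.hidden_units] * config.n_hidden_layers
        self.hidden = [
            Dense(dims[i], dims[i + 1], rng, bias=config.bias)
            for i in range(config.n_hidden_layers)
        ]
        self.head = Dense(dims[-1], out_dim, rng, bias=config.bias)
        self.drops = [
            Dropout(config.dropout, rng) for _ in range(config.n_hidden_layers + 1)
        ]
        self.n_classes = config.n_classes

    def logits(self, X: Tensor, train: bool) -> Tensor:
        h = X
        for layer, drop in zip(self.hidden, self.drops[:-1]):
            h = layer(drop(h, train)).relu()
        return self.head(self.drops[-1](h, train))


def _masked_loss(model: MLPModel, X: Tensor, labels, mask, train: bool) -> Tensor:
    logits = model.logits(X, train)
    rows = np.flatnonzero(mask)
    y = labels[rows]
    if model.n_classes == 2:
        z = take_pairs(logits, rows, np.zeros(len(rows), dtype=int))
        return (softplus(z) - z * y.astype(float)).mean()
    return -take_pairs(log_softmax(logits, axis=1), rows, y).mean()


def _encode(labels: np.ndarray, n_classes: int) -> np.ndarray:
    uniq = np.unique(labels)
    if len(uniq) != n_classes:
        raise ValueError(f"found {len(uniq)} label values, config says {n_classes}")
    lut = {v: i for i, v in enumerate(uniq)}
    return np.array([lut[v] for v in labels])


def train_mlp(
    X: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    val_mask: np.ndarray,
    config: MLPConfig,
) -> tuple[MLPModel, TrainState]:
    """Full-batch masked training with early stopping (same regimen as the GCN)."""
    y = _encode(np.asarray(labels), config.n_classes)
    model = MLPModel(X.shape[1], config)
    opt = Adam(model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay)
    Xt = Tensor(np.asarray(X, float))

    def train_epoch() -> float:
        opt.zero_grad()
        loss = _masked_loss(model, Xt, y, train_mask, train=True)
        loss.backward()
        opt.step()
        return float(loss.data)

    def val_loss() -> float:
        return float(_masked_loss(model, Xt, y, val_mask, train=False).data)

    state = fit_early_stopping(model, train_epoch, val_loss, config.max_epochs, config.patience)
    return model, state


def predict_mlp(
    model: MLPModel, X: np.ndarray, labels_domain: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels + scores; binary 0.5 boundary maps to the advanced stage."""
    logits = model.logits(Tensor(np.asarray(X, float)), train=False).data
    uniq = np.unique(labels_domain)
    if model.n_classes == 2:
        scores = 1.0 / (1.0 + np.exp(-logits))
        preds = uniq[(scores[:, 0] >= 0.5).astype(int)]
    else:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        scores = e / e.sum(axis=1, keepdims=True)
        preds = uniq[scores.argmax(axis=1)]
    if mask is not None:
        mask = np.asarray(mask, bool)
        return preds[mask], scores[mask]
    return preds, scores
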