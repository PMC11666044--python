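"""Two-layer graph convolutional network for transductive node classification.

The forward pass is Z = head(A_hat @ ReLU(A_hat @ X @ W0) @ W1) with the
symmetric-normalized adjacency A_hat; the head is a softmax over C classes,
or a single-logit sigmoid for binary tasks so that binary cross-entropy
applies literally.  Training is full-batch on the whole population graph with
the loss masked to training nodes, Adam with weight decay, and early stopping
on the validation-mask loss; test labels never influence training
(transductive semi-supervised learning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Dense, Dropout, Module, Tensor, TrainState, fit_early_stopping
from .nn.autodiff import log_softmax, softplus, take_pairs
from .popgraph import PopulationGraph

__all__ = [
    "GCNConfig",
    "GCNParams",
    "GCNModel",
    "gcn_forward",
    "masked_loss",
    "train_gcn",
    "predict",
]

_EPS = 1e-12


@dataclass
class GCNConfig:
    hidden_units: int = 64
    learning_rate: float = 1e-3
    dropout: float = 0.2
    weight_decay: float = 1e-5
    max_epochs: int = 500
    patience: int = 20
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class GCNParams:
    W0: np.ndarray  # input_dim x H
    W1: np.ndarray  # H x out_dim (1 for binary, C for multiclass)

    @property
    def out_dim(self) -> int:
        return self.W1.shape[1]


class GCNModel(Module):
    """Two graph-convolution layers; dropout on each layer's input."""

    def __init__(self, input_dim: int, config: GCNConfig):
        rng = np.random.default_rng(config.seed)
        out_dim = 1 if config.n_classes == 2 else config.n_classes
        self.layer0 = Dense(input_dim, config.hidden_units, rng, bias=False)
        self.layer1 = Dense(config.hidden_units, out_dim, rng, bias=False)
        self.drop0 = Dropout(config.dropout, rng)
        self.drop1 = Dropout(config.dropout, rng)
        self.n_classes = config.n_classes

    def logits(self, X: Tensor, A_hat: Tensor, train: bool) -> Tensor:
        h = A_hat @ self.layer0(self.drop0(X, train))
        h = h.relu()
        return A_hat @ self.layer1(self.drop1(h, train))

    def params_view(self) -> GCNParams:
        return GCNParams(W0=self.layer0.weight.data.copy(), W1=self.layer1.weight.data.copy())


def _head(logits: np.ndarray, n_classes: int) -> np.ndarray:
    if n_classes == 2:
        return 1.0 / (1.0 + np.exp(-logits))  # sigmoid, (N, 1)
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(
    X: np.ndarray,
    A_hat: np.ndarray,
    params: GCNParams,
    dropout_active: bool = False,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class-probability matrix Z for every node (sigmoid column if binary)."""
    X = np.asarray(X, float)
    A_hat = np.asarray(A_hat, float)
    if X.shape[0] != A_hat.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but A_hat is {A_hat.shape[0]}x{A_hat.shape[1]}"
        )
    if X.shape[1] != params.W0.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns but W0 expects {params.W0.shape[0]}"
        )
    h = X
    if dropout_active and dropout > 0.0:
        if rng is None:
            raise ValueError("dropout_active requires an rng")
        h = h * ((rng.random(h.shape) < 1.0 - dropout) / (1.0 - dropout))
    h = np.maximum(A_hat @ h @ params.W0, 0.0)
    if dropout_active and dropout > 0.0:
        h = h * ((rng.random(h.shape) < 1.0 - dropout) / (1.0 - dropout))
    logits = A_hat @ h @ params.W1
    n_classes = 2 if params.out_dim == 1 else params.out_dim
    return _head(logits, n_classes)


def masked_loss(Z: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    """Mean cross-entropy over masked nodes (probabilities in, clamped)."""
    Z = np.asarray(Z, float)
    labels = np.asarray(labels)
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no nodes")
    Zm = Z[mask]
    y = labels[mask]
    if Z.shape[1] == 1:  # binary, sigmoid scores; labels in {0,1}
        p = np.clip(Zm[:, 0], _EPS, 1.0 - _EPS)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    p = np.clip(Zm[np.arange(len(y)), y], _EPS, None)
    return float(-np.mean(np.log(p)))


def _masked_loss_graph(model: GCNModel, X, A_hat, labels, mask, train: bool) -> Tensor:
    """Differentiable masked cross-entropy from logits (numerically stable)."""
    logits = model.logits(X, A_hat, train)
    rows = np.flatnonzero(mask)
    y = labels[rows]
    if model.n_classes == 2:
        z = take_pairs(logits, rows, np.zeros(len(rows), dtype=int))
        # BCE with logits: softplus(z) - y*z
        return (softplus(z) - z * y.astype(float)).mean()
    lp = log_softmax(logits, axis=1)
    return -take_pairs(lp, rows, y).mean()


def _encode_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Map arbitrary sorted label values to 0..C-1 (advanced stage = higher)."""
    uniq = np.unique(labels)
    if len(uniq) != n_classes:
        raise ValueError(f"found {len(uniq)} label values, config says {n_classes}")
    lut = {v: i for i, v in enumerate(uniq)}
    return np.array([lut[v] for v in labels])


def train_gcn(graph: PopulationGraph, config: GCNConfig) -> tuple[GCNParams, TrainState]:
    """Full-batch semi-supervised training with early stopping.

    The loss is masked to training nodes; the validation-mask loss drives
    early stopping and best-epoch selection.
    """
    if graph.train_mask.sum() == 0 or graph.val_mask.sum() == 0:
        raise ValueError("train and val masks must be non-empty")
    y = _encode_labels(graph.labels, config.n_classes)
    model = GCNModel(graph.X.shape[1], config)
    opt = Adam(model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay)
    X = Tensor(graph.X)
    A_hat = Tensor(graph.A_hat)

    def train_epoch() -> float:
        opt.zero_grad()
        loss = _masked_loss_graph(model, X, A_hat, y, graph.train_mask, train=True)
        loss.backward()
        opt.step()
        return float(loss.data)

    def val_loss() -> float:
        loss = _masked_loss_graph(model, X, A_hat, y, graph.val_mask, train=False)
        return float(loss.data)

    state = fit_early_stopping(model, train_epoch, val_loss, config.max_epochs, config.patience)
    return model.params_view(), state


def predict(
    graph: PopulationGraph, params: GCNParams, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (original label values) and class scores for masked nodes.

    Binary scores >= 0.5 map to the more advanced stage; multiclass argmax
    ties break toward the lowest class index.
    """
    Z = gcn_forward(graph.X, graph.A_hat, params, dropout_active=False)
    uniq = np.unique(graph.labels)
    if params.out_dim == 1:
        pred_codes = (Z[:, 0] >= 0.5).astype(int)
    else:
        pred_codes = Z.argmax(axis=1)
    preds = uniq[pred_codes]
    if mask is not None:
        mask = np.asarray(mask, bool)
        return preds[mask], Z[mask]
    return preds, Z
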