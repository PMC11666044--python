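"""3-D DenseNet-BC feature extractor for volumetric PET images.

Architecture: an initial 3x3x3 convolution producing ``2k`` channels, then
alternating dense blocks and transition layers, global average pooling, two
fully-connected layers, and a classification head.  Inside a dense block each
layer applies the composite BN - ReLU - 1x1x1 conv (bottleneck, ``b*k``
maps) - BN - ReLU - 3x3x3 conv (``k`` maps) to the concatenation of the block
input and all preceding layer outputs, so channel counts grow by the growth
rate ``k`` per layer.  A transition layer compresses channels to
``floor(theta * m)`` with a 1x1x1 convolution after BN - ReLU and halves each
spatial dimension with 2x2x2 average pooling (stride 2).

After training (Adam, weight decay, early stopping on validation loss) the
network serves as a feature extractor: the first fully-connected layer's
post-ReLU activations are the per-subject imaging feature vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm3d,
    Conv3d,
    Dense,
    Dropout,
    Module,
    Tensor,
    TrainState,
    avg_pool3d_2x,
    fit_early_stopping,
    global_avg_pool3d,
)
from .nn.autodiff import concat, log_softmax, softplus, take_pairs

__all__ = [
    "DenseNetConfig",
    "DenseNet3D",
    "FeatureExtractor",
    "dense_block_channels",
    "transition_channels",
    "channel_trace",
    "build_extractor",
    "train_extractor",
    "extract_features",
    "predict_extractor",
]


@dataclass
class DenseNetConfig:
    growth_rate: int = 32
    bottleneck_multiplier: int = 4
    compression: float = 0.5
    block_layout: tuple[int, ...] = (3, 6, 12, 8)
    initial_channels: int | None = None  # defaults to 2 * growth_rate
    fc1_units: int = 256
    fc2_units: int = 64
    dropout: float = 0.2
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 20
    weight_decay: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.growth_rate < 1 or self.bottleneck_multiplier < 1:
            raise ValueError("growth_rate and bottleneck_multiplier must be positive")
        if not 0.0 < self.compression < 1.0:
            raise ValueError(f"compression must be in (0, 1), got {self.compression}")
        if len(self.block_layout) < 1 or any(l < 0 for l in self.block_layout):
            raise ValueError("block_layout must list non-negative layer counts")
        if self.fc1_units < 1 or self.fc2_units < 1:
            raise ValueError("fc widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.initial_channels is None:
            object.__setattr__(self, "initial_channels", 2 * self.growth_rate)


def dense_block_channels(m_in: int, n_layers: int, k: int) -> int:
    """Output channel count of a dense block: each layer concatenates k maps."""
    if m_in < 1 or k < 1 or n_layers < 0:
        raise ValueError("channel counts and growth rate must be positive")
    return m_in + n_layers * k


def transition_channels(m: int, theta: float) -> int:
    """Compressed channel count floor(theta * m) after a transition layer."""
    if m < 1:
        raise ValueError("input channel count must be >= 1")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"compression must be in (0, 1), got {theta}")
    return math.floor(theta * m)


class _DenseLayer(Module):
    """BN-ReLU-1x1x1 conv (b*k maps) - BN-ReLU-3x3x3 conv (k maps)."""

    def __init__(self, in_channels: int, k: int, b: int, rng):
        self.bn1 = BatchNorm3d(in_channels)
        self.conv1 = Conv3d(in_channels, b * k, 1, rng)
        self.bn2 = BatchNorm3d(b * k)
        self.conv2 = Conv3d(b * k, k, 3, rng, padding=1)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        h = self.conv1(self.bn1(x, train).relu())
        return self.conv2(self.bn2(h, train).relu())


class _DenseBlock(Module):
    def __init__(self, in_channels: int, n_layers: int, k: int, b: int, rng):
        self.layers = [
            _DenseLayer(in_channels + i * k, k, b, rng) for i in range(n_layers)
        ]

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else concat(feats, axis=1)
            feats.append(layer(inp, train))
        return feats[0] if len(feats) == 1 else concat(feats, axis=1)


class _Transition(Module):
    def __init__(self, in_channels: int, theta: float, rng):
        self.bn = BatchNorm3d(in_channels)
        self.conv = Conv3d(in_channels, transition_channels(in_channels, theta), 1, rng)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        return avg_pool3d_2x(self.conv(self.bn(x, train).relu()))


class DenseNet3D(Module):
    def __init__(self, config: DenseNetConfig, n_classes: int):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        rng = np.random.default_rng(config.seed)
        k, b, theta = config.growth_rate, config.bottleneck_multiplier, config.compression
        self.conv0 = Conv3d(1, config.initial_channels, 3, rng, padding=1)
        self.blocks: list[_DenseBlock] = []
        self.transitions: list[_Transition] = []
        m = config.initial_channels
        for i, n_layers in enumerate(config.block_layout):
            self.blocks.append(_DenseBlock(m, n_layers, k, b, rng))
            m = dense_block_channels(m, n_layers, k)
            if i < len(config.block_layout) - 1:
                self.transitions.append(_Transition(m, theta, rng))
                m = transition_channels(m, theta)
        self.final_bn = BatchNorm3d(m)
        self.fc1 = Dense(m, config.fc1_units, rng)
        self.fc2 = Dense(config.fc1_units, config.fc2_units, rng)
        out_dim = 1 if n_classes == 2 else n_classes
        self.head = Dense(config.fc2_units, out_dim, rng)
        self.drop1 = Dropout(config.dropout, rng)
        self.drop2 = Dropout(config.dropout, rng)
        self.n_classes = n_classes
        self.config = config

    def _trunk(self, x: Tensor, train: bool) -> Tensor:
        h = self.conv0(x)
        for i, block in enumerate(self.blocks):
            h = block(h, train)
            if i < len(self.transitions):
                h = self.transitions[i](h, train)
        h = self.final_bn(h, train).relu()
        return global_avg_pool3d(h)

    def fc1_features(self, x: Tensor, train: bool = False) -> Tensor:
        return self.fc1(self._trunk(x, train)).relu()

    def logits(self, x: Tensor, train: bool) -> Tensor:
        h = self.drop1(self.fc1_features(x, train), train)
        h = self.drop2(self.fc2(h).relu(), train)
        return self.head(h)


@dataclass
class FeatureExtractor:
    config: DenseNetConfig
    model: DenseNet3D
    input_shape: tuple[int, int, int]
    n_classes: int
    training_history: TrainState | None = None

    @property
    def trained(self) -> bool:
        return self.training_history is not None


def channel_trace(config: DenseNetConfig) -> list[int]:
    """Analytic channel counts entering/leaving each stage of the network."""
    trace = [config.initial_channels]
    m = config.initial_channels
    for i, n_layers in enumerate(config.block_layout):
        m = dense_block_channels(m, n_layers, config.growth_rate)
        trace.append(m)
        if i < len(config.block_layout) - 1:
            m = transition_channels(m, config.compression)
            trace.append(m)
    return trace


def build_extractor(
    config: DenseNetConfig,
    n_classes: int,
    input_shape: tuple[int, int, int] = (64, 64, 64),
) -> FeatureExtractor:
    """Build an untrained extractor, checking the volume supports the pooling depth."""
    n_trans = len(config.block_layout) - 1
    factor = 2 ** n_trans
    if any(s % factor != 0 or s < 2 * factor for s in input_shape):
        raise ValueError(
            f"input shape {input_shape} too small for {len(config.block_layout)} "
            f"dense blocks: each axis must be a multiple of {factor} and >= {2 * factor}"
        )
    return FeatureExtractor(
        config=config,
        model=DenseNet3D(config, n_classes),
        input_shape=tuple(input_shape),
        n_classes=n_classes,
    )


def _as_batch_tensor(volumes: np.ndarray) -> Tensor:
    v = np.asarray(volumes, float)
    return Tensor(v[:, None])  # add channel axis


def _batch_loss(model: DenseNet3D, x: Tensor, y: np.ndarray, train: bool) -> Tensor:
    logits = model.logits(x, train)
    rows = np.arange(len(y))
    if model.n_classes == 2:
        z = take_pairs(logits, rows, np.zeros(len(y), dtype=int))
        return (softplus(z) - z * y.astype(float)).mean()
    return -take_pairs(log_softmax(logits, axis=1), rows, y).mean()


def train_extractor(
    extractor: FeatureExtractor,
    volumes: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
) -> FeatureExtractor:
    """Train with Adam + weight decay, early-stopped on validation loss.

    Binary tasks use binary cross-entropy on a single sigmoid logit;
    multiclass tasks use categorical cross-entropy.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and val indices must be disjoint")
    labels = np.asarray(labels)
    uniq = np.unique(labels[train_idx])
    if len(uniq) < 2:
        raise ValueError("training set must contain at least 2 classes")
    codes = _codes(labels, extractor.n_classes)
    cfg = extractor.config
    model = extractor.model
    opt = Adam(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    volumes = np.asarray(volumes, float)
    _check_shape(extractor, volumes)
    rng = np.random.default_rng(cfg.seed + 1)

    def train_epoch() -> float:
        order = rng.permutation(train_idx)
        losses, weights = [], []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = _batch_loss(model, _as_batch_tensor(volumes[idx]), codes[idx], train=True)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            weights.append(len(idx))
        return float(np.average(losses, weights=weights))

    def val_loss() -> float:
        losses, weights = [], []
        for start in range(0, len(val_idx), cfg.batch_size):
            idx = val_idx[start : start + cfg.batch_size]
            loss = _batch_loss(model, _as_batch_tensor(volumes[idx]), codes[idx], train=False)
            losses.append(float(loss.data))
            weights.append(len(idx))
        return float(np.average(losses, weights=weights))

    extractor.training_history = fit_early_stopping(
        model, train_epoch, val_loss, cfg.max_epochs, cfg.patience
    )
    return extractor


def _codes(labels: np.ndarray, n_classes: int) -> np.ndarray:
    uniq = np.unique(labels)
    if len(uniq) > n_classes:
        raise ValueError(f"{len(uniq)} label values but head built for {n_classes}")
    lut = {v: i for i, v in enumerate(uniq)}
    return np.array([lut[v] for v in labels])


def _check_shape(extractor: FeatureExtractor, volumes: np.ndarray) -> None:
    if volumes.ndim != 4 or volumes.shape[1:] != extractor.input_shape:
        raise ValueError(
            f"expected volumes of shape (N, {', '.join(map(str, extractor.input_shape))}), "
            f"got {volumes.shape}"
        )


def extract_features(
    extractor: FeatureExtractor, volumes: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    """N x fc1_units matrix of first-FC-layer activations (inference mode)."""
    volumes = np.asarray(volumes, float)
    _check_shape(extractor, volumes)
    out = []
    for start in range(0, len(volumes), batch_size):
        x = _as_batch_tensor(volumes[start : start + batch_size])
        out.append(extractor.model.fc1_features(x, train=False).data)
    return np.vstack(out)


def predict_extractor(
    extractor: FeatureExtractor, volumes: np.ndarray, labels_domain: np.ndarray,
    batch_size: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and scores from the extractor's own classification head."""
    volumes = np.asarray(volumes, float)
    _check_shape(extractor, volumes)
    uniq = np.unique(labels_domain)
    preds, scores = [], []
    for start in range(0, len(volumes), batch_size):
        x = _as_batch_tensor(volumes[start : start + batch_size])
        logits = extractor.model.logits(x, train=False).data
        if extractor.n_classes == 2:
            p = 1.0 / (1.0 + np.exp(-logits))
            preds.append(uniq[(p[:, 0] >= 0.5).astype(int)])
            scores.append(p)
        else:
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            preds.append(uniq[p.argmax(axis=1)])
            scores.append(p)
    return np.concatenate(preds), np.vstack(scores)
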