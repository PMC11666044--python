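"""Shared early-stopping training loop.

The regimen is the same for every gradient-trained model in the package:
Adam, at most ``max_epochs`` epochs, training halted once the validation
loss has failed to decrease for ``patience`` consecutive epochs, and the
parameters of the epoch with the minimum validation loss retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .modules import Module

__all__ = ["TrainState", "fit_early_stopping"]


@dataclass
class TrainState:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_epoch: int = 0

    @property
    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch - 1]


def fit_early_stopping(
    model: Module,
    train_epoch: Callable[[], float],
    val_loss: Callable[[], float],
    max_epochs: int,
    patience: int,
) -> TrainState:
    """Run ``train_epoch`` until early stopping triggers; restore best weights.

    ``train_epoch`` performs one full epoch of optimisation and returns the
    training loss; ``val_loss`` evaluates the current model on the validation
    set without updating it.
    """
    if max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    state = TrainState()
    best = np.inf
    best_snapshot = model.get_state()
    stall = 0
    for epoch in range(1, max_epochs + 1):
        tl = float(train_epoch())
        vl = float(val_loss())
        if not np.isfinite(tl) or not np.isfinite(vl):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} (train={tl}, val={vl})"
            )
        state.train_losses.append(tl)
        state.val_losses.append(vl)
        if vl < best:
            best = vl
            state.best_epoch = epoch
            best_snapshot = model.get_state()
            stall = 0
        else:
            stall += 1
        state.stopped_epoch = epoch
        if stall >= patience:
            break
    model.set_state(best_snapshot)
    return state
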