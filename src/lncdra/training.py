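"""Loss computation and the full-batch optimization loop.

Training is matrix completion: the encoder embeds both node sets from the
training matrix's GIP similarity graphs, the decoder scores every pair, and
the loss is evaluated only on the masked (training) entries.  The default
objective is mean binary cross-entropy; mean squared error is selectable;
the signed residual sum is retained purely as a diagnostic (it is unbounded
below and is never optimized).  All randomness — initialization, dropout —
derives from the config seed, and the graphs are small enough that each
epoch is one full-batch Adam step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor
from .config import TrainConfig
from .data_io import AssociationMatrix
from .errors import ContractError, DivergenceError
from .model import ModelParams, _encode_t, _score_t, init_params

__all__ = ["TrainHistory", "reconstruction_loss", "train_model"]

_EPS = 1e-7  # probability clamp for BCE


@dataclass
class TrainHistory:
    """Per-epoch loss trace (and optional validation metrics)."""

    loss: list[float] = field(default_factory=list)
    val_metrics: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


def _mask_arrays(mask: Sequence[tuple[int, int]],
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    if len(mask) == 0:
        raise ContractError("entry mask is empty")
    idx = np.asarray(sorted(mask), dtype=int)
    if idx.ndim != 2 or idx.shape[1] != 2:
        raise ContractError("mask must be a set of (row, column) pairs")
    rows, cols = idx[:, 0], idx[:, 1]
    if rows.min() < 0 or rows.max() >= shape[0] or \
            cols.min() < 0 or cols.max() >= shape[1]:
        raise ContractError("mask indexes outside the matrix")
    return rows, cols


def _loss_t(scores: Tensor, targets: np.ndarray, rows: np.ndarray,
            cols: np.ndarray, variant: str) -> Tensor:
    s = scores.gather(rows, cols)
    t = Tensor(targets[rows, cols])
    if variant == "bce":
        p = s.clip(_EPS, 1.0 - _EPS)
        ll = t * p.log() + (1.0 - t) * (1.0 - p).log()
        return -ll.mean()
    if variant == "mse":
        d = s - t
        return (d * d).mean()
    if variant == "literal_sum":
        return (s - t).sum()
    raise ContractError(f"unknown loss variant {variant!r}")


def reconstruction_loss(scores: np.ndarray, matrix: AssociationMatrix,
                        mask: Sequence[tuple[int, int]],
                        variant: str = "bce") -> float:
    """Reconstruction loss over the masked entries.

    bce: mean of -[A log A' + (1-A) log(1-A')], probabilities clamped to
    [1e-7, 1-1e-7].  mse: mean squared residual.  literal_sum: the signed
    residual sum (diagnostic only).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != matrix.A.shape:
        raise ContractError("score shape does not match matrix shape")
    rows, cols = _mask_arrays(mask, scores.shape)
    return float(_loss_t(Tensor(scores), matrix.A, rows, cols, variant).data)


def train_model(matrix: AssociationMatrix,
                train_mask: Sequence[tuple[int, int]],
                config: TrainConfig,
                callback=None) -> tuple[ModelParams, TrainHistory]:
    """Optimize the encoder with Adam against the configured loss.

    `matrix` must already be the training view (test positives zeroed by the
    caller): both the loss and the GIP similarity graphs are built from it,
    so held-out entries influence neither.  `train_mask` is the set of
    (row, column) entries the loss is evaluated on.  `epochs=0` returns the
    seeded initialization with an empty history.
    """
    rows, cols = _mask_arrays(train_mask, matrix.A.shape)
    targets = matrix.A
    pos = targets[rows, cols].sum()
    if config.epochs > 0 and (pos == 0 or pos == len(rows)):
        raise ContractError(
            "training mask needs at least one positive and one negative entry")
    if config.loss_variant == "literal_sum":
        raise ContractError(
            "literal_sum is a diagnostic; train with bce or mse")

    rng = np.random.default_rng(config.seed)
    params = init_params(matrix.m, matrix.n, config, rng)
    opt = Adam(params.tensors, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    history = TrainHistory()
    dropout_rng = rng if config.dropout > 0 else None
    for epoch in range(config.epochs):
        opt.zero_grad()
        Xl, Xd = _encode_t(matrix, config, params, rng=dropout_rng)
        scores = _score_t(Xl, Xd)
        loss = _loss_t(scores, targets, rows, cols, config.loss_variant)
        value = float(loss.data)
        if not np.isfinite(value):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        loss.backward()
        opt.step()
        history.loss.append(value)
        if callback is not None:
            callback(epoch, value)
    return params, history
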