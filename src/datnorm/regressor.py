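"""Feed-forward regressor from frozen embeddings to normative atlas values.

The regressor shares the adversarial-head architecture (hidden blocks of
linear → layer norm → ReLU → dropout) with a scalar output, minimizes
mean-squared error over mini-batches with decoupled-weight-decay Adam, and
anneals the learning rate to zero with a cosine schedule over the configured
epochs.  Predictions are mapped back to the original binding-potential scale
through the stored atlas standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import RegressorConfig
from .nn import MLP, AdamW, cosine_lr, mse_loss
from .preprocess import AtlasScaler

__all__ = ["RegressorState", "train_regressor", "predict_dat"]


@dataclass
class RegressorState:
    model: MLP
    config: RegressorConfig
    loss_trace: np.ndarray  # one mean loss per epoch
    final_loss: float
    seed: int


def train_regressor(
    embeddings: np.ndarray, targets: np.ndarray, config: RegressorConfig
) -> RegressorState:
    """Fit the MSE regressor on standardized targets; deterministic given seed."""
    x = np.asarray(embeddings, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("embeddings and targets disagree in length")
    if x.shape[1] != config.input_dim:
        raise ValueError(
            f"embedding dimension {x.shape[1]} != config.input_dim {config.input_dim}"
        )
    if abs(y.mean()) > 0.1 or abs(y.var() - 1.0) > 0.2:
        warnings.warn(
            "regression targets do not look standardized "
            f"(mean {y.mean():.3f}, var {y.var():.3f})",
            stacklevel=2,
        )

    root = np.random.SeedSequence([config.seed, 0x4E6])
    ss_init, ss_shuffle, ss_drop = root.spawn(3)
    rng_shuffle = np.random.default_rng(ss_shuffle)
    rng_drop = np.random.default_rng(ss_drop)
    x32 = x.astype(np.float32)
    y32 = y.astype(np.float32)
    model = MLP(
        config.input_dim,
        tuple(config.hidden),
        1,
        block_order="ln_relu",
        dropout=config.dropout,
    ).init(np.random.default_rng(ss_init), dtype=np.float32)
    opt = AdamW(model.params, lr=config.lr, weight_decay=config.weight_decay)

    n = x.shape[0]
    batches_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    total_steps = config.epochs * batches_per_epoch
    trace = np.empty(config.epochs)
    step = 0
    for epoch in range(config.epochs):
        order = rng_shuffle.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred, cache = model.forward(x32[idx], train=True, rng=rng_drop)
            loss, d_pred = mse_loss(pred[:, 0], y32[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at step {step}")
            grads, _ = model.backward(cache, d_pred[:, None])
            opt.step(model.params, grads, lr=cosine_lr(step, total_steps, config.lr))
            epoch_losses.append(loss)
            step += 1
        trace[epoch] = float(np.mean(epoch_losses))

    model.dropout = 0.0
    return RegressorState(
        model=model,
        config=config,
        loss_trace=trace,
        final_loss=float(trace[-1]),
        seed=config.seed,
    )


def predict_dat(
    state: RegressorState,
    embeddings: np.ndarray,
    atlas_scaler: AtlasScaler | None,
) -> np.ndarray:
    """Predict DaT values on the original binding-potential scale.

    Pass ``atlas_scaler=None`` to obtain raw (standardized-scale) network
    outputs instead.
    """
    pred, _ = state.model.forward(np.asarray(embeddings, dtype=float), train=False)
    out = pred[:, 0]
    if atlas_scaler is None:
        return out
    return atlas_scaler.inverse(out)
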