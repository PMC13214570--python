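"""Minimal feed-forward network core with explicit reverse-mode gradients.

Implements exactly the pieces the embedding/regression pipeline needs —
dense layers, ReLU, layer normalization, inverted dropout, row-wise L2
normalization, softmax cross-entropy, InfoNCE, mean-squared error, and a
decoupled-weight-decay Adam optimizer with an optional cosine learning-rate
schedule.  Forward passes cache intermediates; ``backward`` consumes the
cache and returns parameter gradients plus the gradient with respect to the
input, which is what lets an adversarial head propagate a sign-flipped
gradient into the encoder (gradient reversal).

All arrays are float64.  Every gradient path is covered by finite-difference
checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "MLP",
    "AdamW",
    "softmax_cross_entropy",
    "info_nce",
    "mse_loss",
    "cosine_lr",
]

_LN_EPS = 1e-5

BlockOrder = Literal["relu_ln", "ln_relu"]


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)


@dataclass
class MLP:
    """Multi-layer perceptron with per-hidden-block ReLU / layer norm / dropout.

    Parameters
    ----------
    input_dim, hidden, output_dim
        Layer widths; ``hidden`` may be empty (a single linear map).
    block_order
        ``"relu_ln"`` applies linear → ReLU → layer norm → dropout per hidden
        block (encoder convention); ``"ln_relu"`` applies linear → layer norm
        → ReLU → dropout (head/regressor convention).
    dropout
        Drop probability for hidden activations during training.
    l2_normalize_output
        If true, output rows are projected onto the unit sphere (contrastive
        embedding convention).
    """

    input_dim: int
    hidden: tuple[int, ...]
    output_dim: int
    block_order: BlockOrder = "relu_ln"
    dropout: float = 0.0
    l2_normalize_output: bool = False
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def init(self, rng: np.random.Generator, dtype=np.float64) -> "MLP":
        widths = [self.input_dim, *self.hidden, self.output_dim]
        p: dict[str, np.ndarray] = {}
        for i, (fi, fo) in enumerate(zip(widths[:-1], widths[1:])):
            p[f"W{i}"] = _he_init(rng, fi, fo).astype(dtype)
            p[f"b{i}"] = np.zeros(fo, dtype=dtype)
            if i < len(widths) - 2:  # hidden blocks carry a layer norm
                p[f"g{i}"] = np.ones(fo, dtype=dtype)
                p[f"beta{i}"] = np.zeros(fo, dtype=dtype)
        self.params = p
        return self

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Run the network; returns ``(output, cache)``.

        Dropout is active only when ``train`` is true, in which case ``rng``
        must be supplied (there is no hidden global randomness).
        """
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise ValueError(
                f"expected input of shape (n, {self.input_dim}), got {x.shape}"
            )
        if train and self.dropout > 0 and rng is None:
            raise ValueError("training-mode forward with dropout requires an rng")
        cache: dict = {"x0": x, "blocks": []}
        h = x
        n_hidden = len(self.hidden)
        for i in range(n_hidden):
            blk: dict = {}
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            blk["in"] = h
            blk["z"] = z
            if self.block_order == "relu_ln":
                a = np.maximum(z, 0.0)
                blk["relu_in"] = z
                ln_out, ln_cache = _layernorm_forward(
                    a, self.params[f"g{i}"], self.params[f"beta{i}"]
                )
                blk["ln"] = ln_cache
                h = ln_out
            else:  # ln_relu
                ln_out, ln_cache = _layernorm_forward(
                    z, self.params[f"g{i}"], self.params[f"beta{i}"]
                )
                blk["ln"] = ln_cache
                blk["relu_in"] = ln_out
                h = np.maximum(ln_out, 0.0)
            if train and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout).astype(h.dtype) / (
                    1.0 - self.dropout
                )
                h = h * mask
                blk["drop_mask"] = mask
            cache["blocks"].append(blk)
        i = n_hidden
        out = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
        cache["final_in"] = h
        if self.l2_normalize_output:
            cache["pre_norm"] = out
            norms = np.linalg.norm(out, axis=1, keepdims=True)
            cache["norms"] = norms
            out = out / norms
            cache["unit"] = out
        return out, cache

    # -- backward ----------------------------------------------------------

    def backward(
        self, cache: dict, grad_out: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backpropagate ``grad_out`` (d loss / d output) through the cache.

        Returns ``(grads, grad_input)`` where ``grads`` has one entry per
        parameter.
        """
        grads: dict[str, np.ndarray] = {}
        g = grad_out
        if self.l2_normalize_output:
            u, norms = cache["unit"], cache["norms"]
            g = (g - u * np.sum(g * u, axis=1, keepdims=True)) / norms
        i = len(self.hidden)
        h = cache["final_in"]
        grads[f"W{i}"] = h.T @ g
        grads[f"b{i}"] = g.sum(axis=0)
        g = g @ self.params[f"W{i}"].T
        for i in range(len(self.hidden) - 1, -1, -1):
            blk = cache["blocks"][i]
            if "drop_mask" in blk:
                g = g * blk["drop_mask"]
            if self.block_order == "relu_ln":
                g, dg, dbeta = _layernorm_backward(g, blk["ln"], self.params[f"g{i}"])
                grads[f"g{i}"] = dg
                grads[f"beta{i}"] = dbeta
                g = g * (blk["relu_in"] > 0)
            else:
                g = g * (blk["relu_in"] > 0)
                g, dg, dbeta = _layernorm_backward(g, blk["ln"], self.params[f"g{i}"])
                grads[f"g{i}"] = dg
                grads[f"beta{i}"] = dbeta
            grads[f"W{i}"] = blk["in"].T @ g
            grads[f"b{i}"] = g.sum(axis=0)
            g = g @ self.params[f"W{i}"].T
        return grads, g

    def copy(self) -> "MLP":
        clone = MLP(
            self.input_dim,
            tuple(self.hidden),
            self.output_dim,
            self.block_order,
            self.dropout,
            self.l2_normalize_output,
        )
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone


def _layernorm_forward(
    x: np.ndarray, gamma: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, dict]:
    d = x.shape[1]
    mu = x.sum(axis=1, keepdims=True)
    mu /= d
    xhat = x - mu
    var = np.einsum("ij,ij->i", xhat, xhat)[:, None]
    var /= d
    inv_std = 1.0 / np.sqrt(var + _LN_EPS, out=var)
    xhat *= inv_std
    return gamma * xhat + beta, {"xhat": xhat, "inv_std": inv_std}


def _layernorm_backward(
    g: np.ndarray, cache: dict, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, inv_std = cache["xhat"], cache["inv_std"]
    d = g.shape[1]
    dgamma = np.einsum("ij,ij->j", g, xhat)
    dbeta = g.sum(axis=0)
    dxhat = g * gamma
    m1 = dxhat.sum(axis=1, keepdims=True)
    m1 /= d
    m2 = np.einsum("ij,ij->i", dxhat, xhat)[:, None]
    m2 /= d
    dxhat -= m1
    dxhat -= xhat * m2
    dxhat *= inv_std
    return dxhat, dgamma, dbeta


# -- losses ----------------------------------------------------------------


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax-normalized logits; returns (loss, dlogits).

    ``labels`` are integer class indices in ``[0, n_classes)``.
    """
    labels = np.asarray(labels)
    n, c = logits.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"label outside class range [0, {c})")
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    log_p = shifted - log_z[:, None]
    loss = -log_p[np.arange(n), labels].mean()
    grad = np.exp(log_p)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def info_nce(z: np.ndarray, tau: float) -> tuple[float, np.ndarray]:
    """Temperature-scaled InfoNCE over a batch of two augmented views.

    ``z`` stacks the 2N unit-norm embeddings as ``[view1; view2]``, so the
    positive partner of row ``i`` is row ``(i + N) mod 2N``.  For each
    sample the denominator runs over all 2N−1 other samples (both views,
    self excluded), with cosine similarity scaled by ``tau``.

    Returns ``(loss, dz)``.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    m = z.shape[0]
    if m < 4 or m % 2:
        raise ValueError("need an even batch of at least 4 embeddings")
    n = m // 2
    rows = np.arange(m)
    pos = (rows + n) % m
    sim = z @ z.T
    sim /= tau
    np.fill_diagonal(sim, -np.inf)
    row_max = sim.max(axis=1, keepdims=True)
    pos_sim = sim[rows, pos].copy()
    # in-place softmax over each row (self excluded via the -inf diagonal)
    np.subtract(sim, row_max, out=sim)
    np.exp(sim, out=sim)
    denom = sim.sum(axis=1)
    loss = -np.mean(pos_sim - row_max[:, 0] - np.log(denom))
    # dL/dsim = (softmax - one-hot(pos)) / m, zero on the (excluded) diagonal
    sim /= denom[:, None]
    sim[rows, pos] -= 1.0
    sim /= m
    np.fill_diagonal(sim, 0.0)
    dz = (sim @ z + sim.T @ z) / tau
    return float(loss), dz


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over the batch; returns (loss, dpred)."""
    diff = np.asarray(pred) - np.asarray(target)
    per_sample = diff**2 if diff.ndim == 1 else (diff**2).sum(axis=1)
    b = diff.shape[0]
    return float(per_sample.mean()), 2.0 * diff / b


# -- optimization ----------------------------------------------------------


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ) -> None:
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(
        self,
        params: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
        lr: float | None = None,
    ) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            p -= lr * (update + self.weight_decay * p)


def cosine_lr(step: int, total_steps: int, base_lr: float) -> float:
    """Cosine annealing from ``base_lr`` at step 0 to 0 at ``total_steps``."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * min(step, total_steps) / total_steps))
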