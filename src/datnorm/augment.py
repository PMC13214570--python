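"""Feature-space augmentations producing stochastic views of voxel signatures.

The augmentation set simulates scanner/batch effects while preserving tissue
identity.  Five transforms are applied in a fixed order, each with magnitude
scaled by a ramped strength in [0, 1]:

1. global multiplicative/additive intensity shift (baseline drift) — one
   scalar gain and offset per voxel, shared across channels;
2. smooth low-rank per-channel gain (coil/spectral-profile variation) —
   ``1 + Σ_r a_r L_r(t)`` with Legendre polynomials over the channel index
   scaled to [−1, 1], independent coefficients per voxel;
3. monotone gamma-like warp (non-linear readout differences) — a single
   exponent per view applied to a per-channel min-max normalized copy and
   mapped back, so it is well defined for signed (z-scored) inputs and
   preserves rank order within every channel;
4. additive Gaussian noise;
5. random feature dropout.

All randomness comes from an explicit generator; two calls with independent
generators yield independent views of the same batch.  At strength 0 the
output equals the input exactly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.polynomial import legendre

from .config import AugmentationConfig

__all__ = ["augment_view", "ramp_strength"]


@lru_cache(maxsize=8)
def _legendre_basis(n_channels: int, rank: int) -> np.ndarray:
    """(channels, rank) matrix of Legendre polynomials of orders 1..rank."""
    t = np.linspace(-1.0, 1.0, n_channels)
    return np.column_stack(
        [legendre.legval(t, np.eye(rank + 1)[r]) for r in range(1, rank + 1)]
    )


def augment_view(
    batch: np.ndarray,
    strength: float,
    rng: np.random.Generator,
    config: AugmentationConfig | None = None,
) -> np.ndarray:
    """Return one augmented view of ``batch`` (voxels × channels)."""
    cfg = config or AugmentationConfig()
    batch = np.asarray(batch)
    if batch.dtype not in (np.float32, np.float64):
        batch = batch.astype(float)
    if not np.isfinite(batch).all():
        raise ValueError("augmentation input contains non-finite values")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    if strength == 0.0:
        return batch.copy()
    n, f = batch.shape
    dt = batch.dtype

    # (i) global multiplicative/additive shift, per voxel
    r = cfg.global_gain_range * strength
    gain = 1.0 - r + 2.0 * r * rng.random((n, 1), dtype=dt)
    offset = (cfg.global_offset_sd * strength) * rng.standard_normal((n, 1), dtype=dt)
    out = batch * gain + offset

    # (ii) smooth low-rank per-channel gain
    basis = _legendre_basis(f, cfg.lowrank_rank).astype(dt)
    coefs = (cfg.lowrank_amplitude * strength) * rng.standard_normal(
        (n, cfg.lowrank_rank), dtype=dt
    )
    out *= 1.0 + coefs @ basis.T

    # (iii) monotone gamma-like warp on a per-channel min-max normalized copy
    gamma = float(np.exp(rng.uniform(-cfg.gamma_log_range, cfg.gamma_log_range) * strength))
    lo = out.min(axis=0, keepdims=True)
    hi = out.max(axis=0, keepdims=True)
    span = hi - lo
    ok = span > 0
    unit = np.where(ok, (out - lo) / np.where(ok, span, 1.0), 0.0)
    out = np.where(ok, lo + span * unit**gamma, out)

    # (iv) additive Gaussian noise
    out += (cfg.noise_sd * strength) * rng.standard_normal(out.shape, dtype=dt)

    # (v) random feature dropout
    p = cfg.dropout_rate * strength
    if p > 0:
        out *= rng.random(out.shape, dtype=dt) >= p
    return out


def ramp_strength(
    step: int, total_steps: int, config: AugmentationConfig | None = None
) -> float:
    """Augmentation strength at a training step, ramped from start to end.

    Non-decreasing in ``step``; equals ``ramp_start`` at step 0 and
    ``ramp_end`` (default 1.0) at ``total_steps``.
    """
    cfg = config or AugmentationConfig()
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError("step must lie in [0, total_steps]")
    frac = step / total_steps
    if cfg.ramp_shape == "cosine":
        frac = 0.5 * (1.0 - np.cos(np.pi * frac))
    return float(cfg.ramp_start + (cfg.ramp_end - cfg.ramp_start) * frac)
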