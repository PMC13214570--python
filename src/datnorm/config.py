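"""Configuration dataclasses for cohort generation, augmentation and training.

Each config validates itself on construction and raises :class:`ConfigError`
naming the offending field.  Two training profiles are provided: ``desk``
(small widths and step counts so the full leave-one-out pipeline runs on a
laptop CPU in seconds per fold) and ``full`` (the production-scale settings:
2048-wide encoder, 512-wide heads, batch 16384, 4000 steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

__all__ = [
    "ConfigError",
    "CohortConfig",
    "AugmentationConfig",
    "EncoderConfig",
    "RegressorConfig",
    "desk_encoder_config",
    "full_encoder_config",
    "desk_regressor_config",
    "full_regressor_config",
]


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic multispectral cohort parameters.

    The defaults define the desk-scale study conditions used throughout the
    test suite: 8 healthy controls (HC) and 4 patients (PD), ~1500 voxels
    per subject on a basal-ganglia-like slab lattice, 40 feature channels,
    and a 30% attenuation of the atlas-linked signal in the putamen-like
    region of PD subjects.
    """

    n_hc: int = 8
    n_pd: int = 4
    n_voxels_per_subject: int = 1500
    n_features: int = 40
    n_rois: int = 3
    disease_attenuation: float = 0.3
    affected_rois: tuple[str, ...] = ("putamen",)
    n_latent: int = 5
    loading_sparsity: float = 0.25
    loading_amplitude: float = 1.0
    tissue_state_noise_sd: float = 0.0
    bias_poly_degree: int = 4
    bias_amplitude: float = 0.5
    residual_bias_amplitude: float = 0.2
    residual_bias_loading_overlap: float = 0.0
    intensity_field_amplitude: float = 0.0
    gain_amplitude: float = 0.1
    noise_sd: float = 0.5
    age_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (22.0, 69.0), "PD": (48.0, 73.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_hc >= 3, "n_hc", "need at least 3 HCs for leave-one-out")
        _require(self.n_pd >= 1, "n_pd", "need at least 1 PD subject")
        _require(self.n_voxels_per_subject >= 64, "n_voxels_per_subject", "too few voxels")
        _require(self.n_features >= 4, "n_features", "too few channels")
        _require(self.n_rois >= 3, "n_rois", "need putamen-like, caudate-like and control ROIs")
        _require(
            0.0 <= self.disease_attenuation <= 1.0,
            "disease_attenuation",
            "must lie in [0, 1]",
        )
        _require(self.bias_poly_degree >= 0, "bias_poly_degree", "must be nonnegative")
        for name in (
            "bias_amplitude",
            "residual_bias_amplitude",
            "intensity_field_amplitude",
            "gain_amplitude",
            "noise_sd",
            "loading_amplitude",
            "tissue_state_noise_sd",
        ):
            _require(getattr(self, name) >= 0, name, "must be nonnegative")
        _require(0.0 < self.loading_sparsity <= 1.0, "loading_sparsity", "must be in (0, 1]")
        _require(
            0.0 <= self.residual_bias_loading_overlap <= 1.0,
            "residual_bias_loading_overlap",
            "must lie in [0, 1]",
        )
        _require(1 <= self.n_latent, "n_latent", "need at least one latent factor")
        for grp in ("HC", "PD"):
            _require(grp in self.age_ranges, "age_ranges", f"missing group {grp}")
            lo, hi = self.age_ranges[grp]
            _require(lo <= hi, "age_ranges", f"{grp} range inverted")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_ranges"] = {k: list(v) for k, v in self.age_ranges.items()}
        d["affected_rois"] = list(self.affected_rois)
        return d


@dataclass(frozen=True)
class AugmentationConfig:
    """Magnitudes of the five feature-space augmentation transforms.

    All magnitudes scale linearly with the ramped strength in ``[0, 1]``;
    at strength 0 every transform is the identity.
    """

    global_gain_range: float = 0.10
    global_offset_sd: float = 0.05
    lowrank_rank: int = 3
    lowrank_amplitude: float = 0.05
    gamma_log_range: float = 0.20
    noise_sd: float = 0.10
    dropout_rate: float = 0.30
    ramp_start: float = 0.2
    ramp_end: float = 1.0
    ramp_shape: str = "linear"

    def __post_init__(self) -> None:
        _require(0.0 <= self.dropout_rate < 1.0, "dropout_rate", "must lie in [0, 1)")
        for name in (
            "global_gain_range",
            "global_offset_sd",
            "lowrank_amplitude",
            "gamma_log_range",
            "noise_sd",
        ):
            _require(getattr(self, name) >= 0, name, "must be nonnegative")
        _require(self.lowrank_rank >= 1, "lowrank_rank", "must be at least 1")
        _require(
            0.0 <= self.ramp_start <= self.ramp_end <= 1.0,
            "ramp_start",
            "need 0 <= start <= end <= 1",
        )
        _require(self.ramp_shape in ("linear", "cosine"), "ramp_shape", "unknown shape")


@dataclass(frozen=True)
class EncoderConfig:
    """Contrastive encoder and adversarial-head training settings."""

    input_dim: int = 349
    hidden: tuple[int, ...] = (2048, 2048, 2048, 2048)
    embed_dim: int = 16
    head_hidden: tuple[int, ...] = (512, 512, 512)
    dropout: float = 0.3
    temperature: float = 0.07
    w_coord: float = 20.0
    w_subject: float = 20.0
    coord_bins: int = 16
    grl_scale: float = 1.0
    steps: int = 4000
    batch_size: int = 16384
    lr: float = 1e-4
    head_lr: float | None = None  # adversarial-head learning rate; None -> lr
    weight_decay: float = 1e-2
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.temperature > 0, "temperature", "must be positive")
        _require(self.embed_dim >= 2, "embed_dim", "must be at least 2")
        _require(self.coord_bins >= 2, "coord_bins", "must be at least 2")
        _require(self.steps >= 1, "steps", "must be at least 1")
        _require(self.batch_size >= 2, "batch_size", "must be at least 2")
        _require(0.0 <= self.dropout < 1.0, "dropout", "must lie in [0, 1)")


@dataclass(frozen=True)
class RegressorConfig:
    """Embedding-to-atlas regressor settings (head architecture, MSE loss)."""

    input_dim: int = 16
    hidden: tuple[int, ...] = (512, 512, 512)
    dropout: float = 0.3
    lr: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 4096
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.epochs >= 1, "epochs", "must be at least 1")
        _require(self.batch_size >= 1, "batch_size", "must be at least 1")
        _require(0.0 <= self.dropout < 1.0, "dropout", "must lie in [0, 1)")


def desk_encoder_config(input_dim: int = 40, **overrides) -> EncoderConfig:
    """Desk-scale encoder profile: small widths, few steps, CPU-friendly."""
    base = dict(
        input_dim=input_dim,
        hidden=(64, 64),
        head_hidden=(64, 64, 64),
        batch_size=256,
        steps=150,
        lr=1e-3,
        head_lr=1e-2,
    )
    base.update(overrides)
    return EncoderConfig(**base)


def full_encoder_config(input_dim: int = 349, **overrides) -> EncoderConfig:
    """Production-scale encoder profile."""
    return EncoderConfig(input_dim=input_dim, **overrides)


def desk_regressor_config(**overrides) -> RegressorConfig:
    base = dict(hidden=(64, 64, 64), batch_size=1024, epochs=30)
    base.update(overrides)
    return RegressorConfig(**base)


def full_regressor_config(**overrides) -> RegressorConfig:
    return RegressorConfig(**overrides)
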