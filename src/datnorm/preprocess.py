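"""Spatial detrending and standardization of voxel signatures.

Smooth location-linked intensity trends (field-inhomogeneity surrogates) are
removed per subject and per channel by least-squares regression on a full
tensor monomial basis of total degree ≤ 4 in the normalized voxel
coordinates — 35 terms in three variables.  Residuals are then z-scored per
subject and per channel (population standard deviation), and the normative
atlas target is standardized over the analysis mask with an invertible
affine map so predictions can be reported back on the original
binding-potential scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import feature_columns

__all__ = [
    "PolynomialBasis",
    "AtlasScaler",
    "polynomial_detrend",
    "zscore_per_subject",
    "standardize_atlas",
    "apply_exclusions",
    "preprocess_table",
]

_DEGENERATE_SD = 1e-12


@dataclass(frozen=True)
class PolynomialBasis:
    """Tensor monomial basis x^a y^b z^c with a+b+c ≤ degree.

    Coordinates are affinely mapped per axis to [−1, 1] over the bounding
    box of the fitted point set before evaluation, for conditioning.
    """

    degree: int = 4
    terms: tuple[tuple[int, int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")
        object.__setattr__(
            self,
            "terms",
            tuple(
                (a, b, c)
                for a in range(self.degree + 1)
                for b in range(self.degree + 1 - a)
                for c in range(self.degree + 1 - a - b)
            ),
        )

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def design_matrix(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        span = hi - lo
        for ax, name in enumerate("xyz"):
            if span[ax] <= 0:
                raise ValueError(
                    f"degenerate coordinate axis {name!r}: all values identical, "
                    "design matrix would be rank deficient"
                )
        u = 2.0 * (coords - lo) / span - 1.0
        cols = [
            u[:, 0] ** a * u[:, 1] ** b * u[:, 2] ** c for a, b, c in self.terms
        ]
        return np.column_stack(cols)


def polynomial_detrend(
    features: np.ndarray, coords: np.ndarray, basis: PolynomialBasis | None = None
) -> np.ndarray:
    """Subtract the least-squares polynomial fit from each feature channel.

    One independent fit per channel over the supplied voxels (intended to be
    a single subject's mask).  Residuals are orthogonal to every basis
    column.  Solved via an SVD-based least-squares factorization rather than
    explicit normal equations.
    """
    basis = basis or PolynomialBasis()
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if not np.isfinite(features).all():
        raise ValueError("features contain non-finite values; drop those voxels first")
    n = features.shape[0]
    if n < basis.n_terms:
        raise ValueError(
            f"need at least {basis.n_terms} voxels to fit a degree-{basis.degree} "
            f"basis, got {n}"
        )
    X = basis.design_matrix(coords)
    coef, _, rank, _ = np.linalg.lstsq(X, features, rcond=None)
    if rank < basis.n_terms:
        raise ValueError(
            f"rank-deficient polynomial design (rank {rank} < {basis.n_terms}); "
            "coordinate grid does not support the basis"
        )
    return features - X @ coef


def zscore_per_subject(
    residuals: np.ndarray,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Z-score each channel over one subject's voxels (population sd).

    Returns the standardized residuals and a stats dict with ``mean``,
    ``sd`` and a boolean ``degenerate`` flag per channel; degenerate
    (zero-variance) channels are returned as zeros and should be excluded
    downstream.
    """
    residuals = np.asarray(residuals, dtype=float)
    if not np.isfinite(residuals).all():
        raise ValueError("residuals contain non-finite values")
    mean = residuals.mean(axis=0)
    sd = residuals.std(axis=0)
    degenerate = sd <= _DEGENERATE_SD
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (residuals - mean) / safe_sd
    z[:, degenerate] = 0.0
    return z, {"mean": mean, "sd": sd, "degenerate": degenerate}


@dataclass(frozen=True)
class AtlasScaler:
    """Invertible affine standardization of the atlas target."""

    mean: float
    sd: float

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, standardized: np.ndarray) -> np.ndarray:
        return np.asarray(standardized, dtype=float) * self.sd + self.mean


def standardize_atlas(values: np.ndarray) -> tuple[np.ndarray, AtlasScaler]:
    """Standardize atlas values to zero mean, unit variance over the mask."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("constant atlas: cannot standardize")
    scaler = AtlasScaler(mean=float(values.mean()), sd=float(values.std()))
    return scaler.transform(values), scaler


def apply_exclusions(
    table: pd.DataFrame,
    excluded_subjects: list[str] | tuple[str, ...] = (),
    excluded_channels: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Drop named subjects (rows) and feature channels (columns).

    Raises on identifiers that do not exist, so typos cannot silently pass.
    """
    subjects = set(table["subject_id"].unique())
    unknown = set(excluded_subjects) - subjects
    if unknown:
        raise KeyError(f"unknown subject id(s): {sorted(unknown)}")
    channels = set(feature_columns(table))
    unknown = set(excluded_channels) - channels
    if unknown:
        raise KeyError(f"unknown channel(s): {sorted(unknown)}")
    out = table[~table["subject_id"].isin(excluded_subjects)]
    if excluded_channels:
        out = out.drop(columns=list(excluded_channels))
    if not excluded_subjects and not excluded_channels:
        return table
    return out.reset_index(drop=True)


def preprocess_table(
    table: pd.DataFrame, degree: int = 4
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Detrend and z-score every subject's features in a long voxel table.

    Channels degenerate for *any* subject are dropped from the output (and
    listed in the returned stats under ``"dropped_channels"``).  Row order,
    coordinates and metadata columns are preserved.
    """
    basis = PolynomialBasis(degree=degree)
    fcols = feature_columns(table)
    out = table.copy()
    stats: dict[str, dict] = {}
    degenerate: set[str] = set()
    for sid, idx in table.groupby("subject_id", sort=False).groups.items():
        sub = table.loc[idx]
        coords = sub[["x", "y", "z"]].to_numpy()
        residuals = polynomial_detrend(sub[fcols].to_numpy(), coords, basis)
        z, st = zscore_per_subject(residuals)
        out.loc[idx, fcols] = z
        stats[str(sid)] = st
        degenerate.update(np.asarray(fcols)[st["degenerate"]])
    if degenerate:
        out = out.drop(columns=sorted(degenerate))
    stats["dropped_channels"] = sorted(degenerate)  # type: ignore[assignment]
    return out, stats
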