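"""Volumetric export of lattice-based voxel tables as NIfTI.

The synthetic lattice is a (possibly trimmed) raster grid in normalized
slab coordinates; volumes are reconstructed by direct coordinate lookup,
with missing lattice points filled with NaN, and a diagonal affine mapping
voxel indices to the normalized coordinates.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["table_to_nifti", "roi_map_to_nifti"]


def _lattice(table: pd.DataFrame):
    axes = []
    for c in ("x", "y", "z"):
        vals = np.unique(table[c].to_numpy())
        axes.append(vals)
    return axes


def _affine(axes) -> np.ndarray:
    aff = np.eye(4)
    for i, vals in enumerate(axes):
        aff[i, i] = vals[1] - vals[0] if len(vals) > 1 else 1.0
        aff[i, 3] = vals[0]
    return aff


def _fill_volume(sub: pd.DataFrame, axes, values: np.ndarray) -> np.ndarray:
    shape = tuple(len(a) for a in axes)
    vol = np.full(shape, np.nan)
    idx = tuple(
        np.searchsorted(axes[i], sub[c].to_numpy()) for i, c in enumerate(("x", "y", "z"))
    )
    vol[idx] = values
    return vol


def table_to_nifti(
    table: pd.DataFrame, subject_id: str, value_col: str, path: str | Path
) -> None:
    """Write one subject's scalar column (prediction, atlas, channel) as NIfTI."""
    sub = table[table["subject_id"] == subject_id]
    if sub.empty:
        raise KeyError(f"unknown subject id {subject_id!r}")
    axes = _lattice(table)
    vol = _fill_volume(sub, axes, sub[value_col].to_numpy(dtype=float))
    nib.save(nib.Nifti1Image(vol, _affine(axes)), str(path))


def roi_map_to_nifti(
    table: pd.DataFrame, path: str | Path
) -> dict[str, int]:
    """Write the shared ROI label map as an integer NIfTI; returns the legend."""
    one = table[table["subject_id"] == table["subject_id"].iloc[0]]
    axes = _lattice(table)
    names = sorted(one["roi"].unique())
    legend = {name: i + 1 for i, name in enumerate(names)}
    codes = one["roi"].map(legend).to_numpy(dtype=float)
    vol = _fill_volume(one, axes, codes)
    nib.save(nib.Nifti1Image(np.nan_to_num(vol), _affine(axes)), str(path))
    return legend
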