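"""Seeded synthetic multispectral cohorts with a plantable putaminal deficit.

The generator emulates, in a common normalized space, the statistical
structure the downstream pipeline assumes about registered multispectral MRI
voxel signatures:

* a shared slab-shaped coordinate lattice (basal-ganglia-like acquisition),
* a smooth nonnegative normative atlas, elevated in striatum-like regions,
* a low-dimensional latent tissue component with smooth spatial maps,
* an atlas-linked signal carried by a sparse subset of channels,
* per-subject smooth polynomial bias fields and per-channel gains
  (field-inhomogeneity and scanner/batch surrogates),
* a per-subject *residual* bias — a smooth spatial field orthogonal to the
  degree-4 polynomial basis times a subject-specific channel direction —
  modeling the nonlinear inhomogeneity that polynomial detrending and
  z-scoring cannot remove (the subject cue the adversarial embedder must
  suppress),
* additive Gaussian measurement noise, and
* a group-specific attenuation of the atlas-linked signal restricted to the
  putamen-like region of patients — the planted disease effect.

Channels are abstract features: no MR physics is simulated.  Everything is
deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig

__all__ = [
    "GroundTruth",
    "generate_cohort",
    "sample_atlas",
    "slab_grid",
    "feature_columns",
    "write_cohort",
    "read_voxel_table",
]

ROI_PUTAMEN = "putamen"
ROI_CAUDATE = "caudate"
ROI_CONTROL = "control"
ROI_BACKGROUND = "background"

# Ellipsoidal ROI geometry in normalized slab coordinates (center, semi-axes).
_ROI_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    ROI_PUTAMEN: ((0.45, 0.10, 0.0), (0.30, 0.40, 0.26)),
    ROI_CAUDATE: ((-0.45, 0.15, 0.0), (0.28, 0.35, 0.26)),
    ROI_CONTROL: ((0.0, -0.55, 0.0), (0.32, 0.30, 0.26)),
}

_YOUNG_HC_AGE_CUTOFF = 40.0


@dataclass
class GroundTruth:
    """Generative parameters stored alongside every cohort for recovery tests."""

    coords: np.ndarray  # (n_vox, 3) shared lattice
    atlas: np.ndarray  # (n_vox,) normative values on the lattice
    roi: np.ndarray  # (n_vox,) ROI label per lattice voxel
    latent_maps: np.ndarray  # (n_vox, n_latent) smooth tissue factors
    mixing: np.ndarray  # (n_latent, n_features)
    loading: np.ndarray  # (n_features,) atlas-linked channel loadings
    loaded_channels: np.ndarray  # indices of the nonzero loadings
    bias_coefs: dict[str, np.ndarray]  # per subject: (n_terms,) spatial field
    bias_channel_weights: dict[str, np.ndarray]  # per subject: (n_features,)
    residual_maps: dict[str, np.ndarray]  # per subject: (n_vox,) non-poly field
    residual_channel_weights: dict[str, np.ndarray]  # per subject: (n_features,)
    intensity_fields: dict[str, np.ndarray]  # per subject: (n_vox,) multiplicative
    gains: dict[str, np.ndarray]  # per subject: (n_features,) multiplicative
    disease_attenuation: float
    affected_rois: tuple[str, ...]

    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()

        return json.dumps(
            {
                "atlas": arr(self.atlas),
                "loading": arr(self.loading),
                "loaded_channels": arr(self.loaded_channels),
                "mixing": arr(self.mixing),
                "bias_coefs": {k: arr(v) for k, v in self.bias_coefs.items()},
                "bias_channel_weights": {
                    k: arr(v) for k, v in self.bias_channel_weights.items()
                },
                "residual_maps": {k: arr(v) for k, v in self.residual_maps.items()},
                "residual_channel_weights": {
                    k: arr(v) for k, v in self.residual_channel_weights.items()
                },
                "gains": {k: arr(v) for k, v in self.gains.items()},
                "disease_attenuation": self.disease_attenuation,
                "affected_rois": list(self.affected_rois),
            }
        )


def slab_grid(n_voxels: int, nz: int = 6) -> np.ndarray:
    """Fixed 3-D lattice inside a slab mask, identical across subjects.

    x and y span [−1, 1]; z spans the thinner slab [−0.3, 0.3].  The lattice
    is trimmed in raster order (z slowest) to exactly ``n_voxels`` points.
    """
    if n_voxels < 8:
        raise ValueError("grid needs at least 8 voxels")
    nxy = int(np.ceil(np.sqrt(n_voxels / nz)))
    xs = np.linspace(-1.0, 1.0, nxy)
    ys = np.linspace(-1.0, 1.0, nxy)
    zs = np.linspace(-0.3, 0.3, nz)
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return coords[:n_voxels]


def assign_rois(coords: np.ndarray, n_rois: int = 3) -> np.ndarray:
    """Label lattice points by ellipsoidal ROI membership; rest is background."""
    labels = np.full(len(coords), ROI_BACKGROUND, dtype=object)
    names = [ROI_PUTAMEN, ROI_CAUDATE, ROI_CONTROL]
    geometry = dict(_ROI_GEOMETRY)
    for k in range(3, n_rois):  # extra control-like regions along the slab edge
        cx = -0.8 + 1.6 * (k - 3) / max(n_rois - 3, 1)
        geometry[f"control{k - 2}"] = ((cx, 0.8, 0.0), (0.2, 0.18, 0.26))
        names.append(f"control{k - 2}")
    for name in names:
        center, axes = geometry[name]
        d = (coords - np.asarray(center)) / np.asarray(axes)
        labels[(d**2).sum(axis=1) <= 1.0] = name
    return labels


def _smooth_field(
    coords: np.ndarray, rng: np.random.Generator, n_bumps: int = 12, width: float = 0.45
) -> np.ndarray:
    """Zero-mean, unit-variance smooth random field: sum of Gaussian bumps."""
    centers = rng.uniform(-1.0, 1.0, size=(n_bumps, 3))
    centers[:, 2] *= 0.3
    amps = rng.standard_normal(n_bumps)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    f = (amps * np.exp(-d2 / (2 * width**2))).sum(axis=1)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def sample_atlas(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Smooth nonnegative normative field, elevated in striatum-like ROIs.

    Peaks near 4 (putamen-like) and 3.5 (caudate-like) on a low background,
    mimicking the contrast of a binding-potential map, plus a mild smooth
    random background so the field is not a pure function of ROI membership.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty coordinate grid")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA71A5]))
    out = np.full(len(coords), 0.3)
    for name, peak in ((ROI_PUTAMEN, 3.7), (ROI_CAUDATE, 3.2)):
        center, axes = _ROI_GEOMETRY[name]
        d2 = (((coords - np.asarray(center)) / np.asarray(axes)) ** 2).sum(axis=1)
        out = out + peak * np.exp(-1.5 * d2)
    out = out + 0.15 * _smooth_field(coords, rng)
    return np.maximum(out, 0.0)


def _polynomial_terms(degree: int) -> list[tuple[int, int, int]]:
    return [
        (a, b, c)
        for a in range(degree + 1)
        for b in range(degree + 1 - a)
        for c in range(degree + 1 - a - b)
    ]


def _poly_design(coords: np.ndarray, degree: int) -> np.ndarray:
    terms = _polynomial_terms(degree)
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    return np.column_stack([x**a * y**b * z**c for a, b, c in terms])


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature-channel columns of a voxel table, in order."""
    return sorted((c for c in table.columns if c.startswith("f") and c[1:].isdigit()),
                  key=lambda c: int(c[1:]))


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one seeded cohort as a long-format voxel table plus ground truth.

    The feature model for subject *s*, voxel *v*, channel *c* is::

        f = G_s(v) * [ (1 + gain[s,c]) * (tissue[v,c] + a(v) * loading[c] * atten(s,v))
                       + bias_s(v) * u[s,c] + r_s(v) * w[s,c] + noise ]

    where ``a(v)`` is the standardized atlas, ``atten`` is
    ``1 − disease_attenuation`` for PD voxels in affected ROIs and 1
    elsewhere, ``bias_s`` is a degree-``bias_poly_degree`` polynomial in the
    normalized coordinates (exactly removable by polynomial detrending),
    ``r_s`` is a smooth residual field orthogonalized against that
    polynomial basis (the subject cue that *survives* detrending),
    ``G_s`` is a smooth positive multiplicative intensity field (a
    receive-field/scanner surrogate — the kind of per-scan distortion the
    contrastive augmentations simulate, multiplicative so neither the
    additive polynomial fit nor per-channel z-scoring can undo it), and
    noise is i.i.d. Gaussian.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    (ss_grid, ss_subjects, ss_struct) = root.spawn(3)
    rng_struct = np.random.default_rng(ss_struct)

    coords = slab_grid(cfg.n_voxels_per_subject)
    n_vox = len(coords)
    roi = assign_rois(coords, cfg.n_rois)
    atlas = sample_atlas(coords, seed=cfg.seed)
    atlas_z = (atlas - atlas.mean()) / atlas.std()

    # latent tissue structure, partly shared with downstream-visible channels
    latent = np.column_stack(
        [_smooth_field(coords, rng_struct) for _ in range(cfg.n_latent)]
    )
    mixing = rng_struct.standard_normal((cfg.n_latent, cfg.n_features)) / np.sqrt(
        cfg.n_latent
    )
    tissue = latent @ mixing

    n_loaded = max(1, int(round(cfg.loading_sparsity * cfg.n_features)))
    loaded = rng_struct.choice(cfg.n_features, size=n_loaded, replace=False)
    loaded.sort()
    loading = np.zeros(cfg.n_features)
    signs = rng_struct.choice([-1.0, 1.0], size=n_loaded)
    loading[loaded] = cfg.loading_amplitude * signs * rng_struct.uniform(
        0.7, 1.3, size=n_loaded
    )

    poly = _poly_design(coords, cfg.bias_poly_degree)
    n_terms = poly.shape[1]
    # projector onto the orthogonal complement of the polynomial span, used
    # to make residual bias fields immune to detrending by construction
    q, _ = np.linalg.qr(poly)
    affected_mask = np.isin(roi, cfg.affected_rois)

    subjects = [f"HC{i + 1:02d}" for i in range(cfg.n_hc)] + [
        f"PD{i + 1:02d}" for i in range(cfg.n_pd)
    ]
    groups = ["HC"] * cfg.n_hc + ["PD"] * cfg.n_pd

    frames: list[pd.DataFrame] = []
    bias_coefs: dict[str, np.ndarray] = {}
    bias_weights: dict[str, np.ndarray] = {}
    residual_maps: dict[str, np.ndarray] = {}
    residual_weights: dict[str, np.ndarray] = {}
    intensity_fields: dict[str, np.ndarray] = {}
    gains: dict[str, np.ndarray] = {}
    subject_streams = ss_subjects.spawn(len(subjects))
    fcols = [f"f{c:03d}" for c in range(cfg.n_features)]

    for sid, grp, ss in zip(subjects, groups, subject_streams):
        rng = np.random.default_rng(ss)
        lo, hi = cfg.age_ranges[grp]
        age = float(rng.uniform(lo, hi))
        gain = cfg.gain_amplitude * rng.standard_normal(cfg.n_features)
        coef = rng.standard_normal(n_terms) / np.sqrt(n_terms)
        weight = cfg.bias_amplitude * rng.standard_normal(cfg.n_features)
        rmap = _smooth_field(coords, rng, n_bumps=16, width=0.3)
        rmap = rmap - q @ (q.T @ rmap)  # strip everything detrending removes
        sd = rmap.std()
        if sd > 0:
            rmap = rmap / sd
        # residual-bias channel direction: a configurable fraction of its
        # energy lies along the atlas loading — scanner bias contaminating
        # the very channels that carry the tissue signal is the hard case
        rdir = rng.standard_normal(cfg.n_features)
        rho = cfg.residual_bias_loading_overlap
        if rho > 0:
            unit_loading = loading / np.linalg.norm(loading)
            rdir -= (rdir @ unit_loading) * unit_loading
            rdir = rho * unit_loading * np.linalg.norm(rdir) * rng.choice([-1, 1]) + np.sqrt(
                1 - rho**2
            ) * rdir
        rweight = cfg.residual_bias_amplitude * rdir
        gfield = np.maximum(
            1.0 + cfg.intensity_field_amplitude * _smooth_field(coords, rng, width=0.4),
            0.1,
        )

        atten = np.ones(n_vox)
        if grp == "PD":
            atten[affected_mask] = 1.0 - cfg.disease_attenuation
        # per-subject tissue state: the atlas-linked biology each voxel
        # actually expresses, with biological variation around the atlas
        state = atlas_z + cfg.tissue_state_noise_sd * rng.standard_normal(n_vox)
        signal = tissue + (state * atten)[:, None] * loading[None, :]
        features = gfield[:, None] * (
            (1.0 + gain)[None, :] * signal
            + np.outer(poly @ coef, weight)
            + np.outer(rmap, rweight)
            + cfg.noise_sd * rng.standard_normal((n_vox, cfg.n_features))
        )

        frame = pd.DataFrame(
            {
                "subject_id": sid,
                "group": grp,
                "age": age,
                "young_hc": grp == "HC" and age < _YOUNG_HC_AGE_CUTOFF,
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
                "roi": roi,
                "atlas": atlas,
            }
        )
        frame[fcols] = features
        frames.append(frame)
        bias_coefs[sid] = coef
        bias_weights[sid] = weight
        residual_maps[sid] = rmap
        residual_weights[sid] = rweight
        intensity_fields[sid] = gfield
        gains[sid] = gain

    table = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        coords=coords,
        atlas=atlas,
        roi=roi,
        latent_maps=latent,
        mixing=mixing,
        loading=loading,
        loaded_channels=loaded,
        bias_coefs=bias_coefs,
        bias_channel_weights=bias_weights,
        residual_maps=residual_maps,
        residual_channel_weights=residual_weights,
        intensity_fields=intensity_fields,
        gains=gains,
        disease_attenuation=cfg.disease_attenuation,
        affected_rois=cfg.affected_rois,
    )
    return table, truth


def write_cohort(table: pd.DataFrame, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write the voxel table as TSV and the ground truth as a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "voxels.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())


def read_voxel_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
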