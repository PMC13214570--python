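"""Contrastive voxel embedder with adversarial coordinate/subject bias removal.

An MLP encoder maps preprocessed multispectral voxel signatures to
L2-normalized 16-D embeddings.  Training minimizes a temperature-scaled
InfoNCE loss over two augmented views of each voxel, plus weighted
cross-entropy losses of two adversarial heads — one predicting the voxel's
discretized coordinates (empirical-quantile bins per axis), one predicting
subject identity — attached through a gradient-reversal layer: the heads are
updated to minimize their own losses, while their gradients reach the
encoder sign-flipped (scaled by −λ), forcing the encoder to hide spatial and
subject cues.  After training the heads are discarded and the encoder is
frozen.

Total loss:  L = L_contrastive + w_c · L_coordinate + w_s · L_subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .augment import augment_view, ramp_strength
from .config import EncoderConfig
from .nn import MLP, AdamW, info_nce, softmax_cross_entropy
from .synthetic import feature_columns

__all__ = [
    "EmbedderState",
    "train_embedder",
    "train_embedder_arrays",
    "encode",
    "encode_table",
    "discretize_coords",
    "quantile_bin_edges",
    "adversarial_losses",
    "save_state",
    "load_state",
]


@dataclass
class EmbedderState:
    """Frozen encoder plus the coordinate-bin edges learned from training data."""

    encoder: MLP
    bin_edges: np.ndarray  # (3, coord_bins + 1), non-decreasing per axis
    config: EncoderConfig
    loss_traces: dict[str, np.ndarray]  # contrastive / coordinate / subject, len=steps
    feature_cols: tuple[str, ...] | None = None
    seed: int = 0


def quantile_bin_edges(coords: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-axis empirical-quantile bin edges from the pooled training coordinates.

    Quantile binning is invariant under the per-axis affine normalization of
    coordinates to [0, 1] (a monotone map commutes with quantiles), so edges
    are computed and stored on the raw coordinate scale of the pooled
    training bounding box.
    """
    coords = np.asarray(coords, dtype=float)
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    return np.stack([np.quantile(coords[:, a], qs) for a in range(3)])


def discretize_coords(coords: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign 1-based quantile-bin labels per axis; out-of-range values clamp
    to the end bins.

    On the training set each bin holds its quantile share of voxels (up to
    ±1 on ties/interpolation).  ``edges`` is the (3, n_bins + 1) array from
    :func:`quantile_bin_edges`.
    """
    coords = np.asarray(coords, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if (np.diff(edges, axis=1) < 0).any():
        raise ValueError("bin edges must be non-decreasing")
    n_bins = edges.shape[1] - 1
    labels = np.empty((len(coords), 3), dtype=int)
    for a in range(3):
        labels[:, a] = np.searchsorted(edges[a, 1:-1], coords[:, a], side="right")
    return np.clip(labels, 0, n_bins - 1) + 1


def adversarial_losses(
    embeddings: np.ndarray,
    coord_labels: np.ndarray,
    subject_labels: np.ndarray,
    coord_head: MLP,
    subject_head: MLP,
    n_bins: int,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Cross-entropy losses of the two adversarial heads on given embeddings.

    ``coord_labels`` are 1-based (n, 3) bin labels; the coordinate loss is
    the mean over the three axis losses.  Returns a dict with the losses,
    per-head parameter gradients, and gradients with respect to the
    embeddings (unreversed).
    """
    coord_labels = np.asarray(coord_labels)
    logits, c_cache = coord_head.forward(embeddings, train=train, rng=rng)
    d_logits = np.zeros_like(logits)
    coord_loss = 0.0
    for a in range(3):
        sl = slice(a * n_bins, (a + 1) * n_bins)
        loss_a, grad_a = softmax_cross_entropy(logits[:, sl], coord_labels[:, a] - 1)
        coord_loss += loss_a / 3.0
        d_logits[:, sl] = grad_a / 3.0
    c_grads, d_emb_coord = coord_head.backward(c_cache, d_logits)

    s_logits, s_cache = subject_head.forward(embeddings, train=train, rng=rng)
    subject_loss, d_s_logits = softmax_cross_entropy(s_logits, subject_labels)
    s_grads, d_emb_subject = subject_head.backward(s_cache, d_s_logits)
    return {
        "coord_loss": coord_loss,
        "subject_loss": subject_loss,
        "coord_grads": c_grads,
        "subject_grads": s_grads,
        "d_emb_coord": d_emb_coord,
        "d_emb_subject": d_emb_subject,
    }


def train_embedder_arrays(
    features: np.ndarray,
    coords: np.ndarray,
    subject_ids: np.ndarray,
    config: EncoderConfig,
) -> EmbedderState:
    """Train the contrastive encoder on raw arrays (one row per voxel)."""
    features = np.asarray(features, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, f = features.shape
    if f != config.input_dim:
        raise ValueError(f"feature dimension {f} != config.input_dim {config.input_dim}")
    uniq, subj_idx = np.unique(np.asarray(subject_ids), return_inverse=True)
    n_subjects = len(uniq)
    if n_subjects < 2:
        raise ValueError("need at least 2 training subjects for the subject head")

    edges = quantile_bin_edges(coords, config.coord_bins)
    coord_labels = discretize_coords(coords, edges)

    root = np.random.SeedSequence([config.seed, 0xE3B])
    ss_init, ss_batch, ss_aug1, ss_aug2, ss_drop = root.spawn(5)
    rng_init = np.random.default_rng(ss_init)
    rng_batch = np.random.default_rng(ss_batch)
    rng_aug1 = np.random.default_rng(ss_aug1)
    rng_aug2 = np.random.default_rng(ss_aug2)
    rng_drop = np.random.default_rng(ss_drop)

    # float32 training: the speed matters, the last 8 digits do not
    dtype = np.float32
    encoder = MLP(
        config.input_dim,
        tuple(config.hidden),
        config.embed_dim,
        block_order="relu_ln",
        dropout=config.dropout,
        l2_normalize_output=True,
    ).init(rng_init, dtype=dtype)
    coord_head = MLP(
        config.embed_dim,
        tuple(config.head_hidden),
        3 * config.coord_bins,
        block_order="ln_relu",
        dropout=config.dropout,
    ).init(rng_init, dtype=dtype)
    subject_head = MLP(
        config.embed_dim,
        tuple(config.head_hidden),
        n_subjects,
        block_order="ln_relu",
        dropout=config.dropout,
    ).init(rng_init, dtype=dtype)

    head_lr = config.head_lr if config.head_lr is not None else config.lr
    opt_enc = AdamW(encoder.params, lr=config.lr, weight_decay=config.weight_decay)
    opt_ch = AdamW(coord_head.params, lr=head_lr, weight_decay=config.weight_decay)
    opt_sh = AdamW(subject_head.params, lr=head_lr, weight_decay=config.weight_decay)

    traces = {k: np.empty(config.steps) for k in ("contrastive", "coordinate", "subject")}
    lam = config.grl_scale
    feats32 = features.astype(dtype)
    # w_c = w_s = 0 is the "no adversarial heads" ablation: the heads are
    # absent, not merely silenced, so their losses are not computed at all
    use_heads = config.w_coord != 0.0 or config.w_subject != 0.0
    if not use_heads:
        traces["coordinate"][:] = np.nan
        traces["subject"][:] = np.nan

    for step in range(config.steps):
        idx = rng_batch.integers(0, n, size=min(config.batch_size, n))
        strength = ramp_strength(step, config.steps, config.augmentation)
        batch = feats32[idx]
        v1 = augment_view(batch, strength, rng_aug1, config.augmentation)
        v2 = augment_view(batch, strength, rng_aug2, config.augmentation)
        views = np.vstack([v1, v2])
        z, enc_cache = encoder.forward(views, train=True, rng=rng_drop)

        con_loss, d_z = info_nce(z, config.temperature)

        if use_heads:
            labels2 = np.concatenate([coord_labels[idx], coord_labels[idx]])
            subj2 = np.concatenate([subj_idx[idx], subj_idx[idx]])
            adv = adversarial_losses(
                z, labels2, subj2, coord_head, subject_head, config.coord_bins,
                train=True, rng=rng_drop,
            )
            # gradient reversal: adversarial gradients reach the encoder
            # sign-flipped
            d_z_enc = d_z - lam * (
                config.w_coord * adv["d_emb_coord"]
                + config.w_subject * adv["d_emb_subject"]
            )
        else:
            d_z_enc = d_z
        enc_grads, _ = encoder.backward(enc_cache, d_z_enc)
        opt_enc.step(encoder.params, enc_grads)
        if use_heads:
            # heads minimize their own (weighted) losses
            opt_ch.step(
                coord_head.params,
                {k: config.w_coord * v for k, v in adv["coord_grads"].items()},
            )
            opt_sh.step(
                subject_head.params,
                {k: config.w_subject * v for k, v in adv["subject_grads"].items()},
            )
            traces["coordinate"][step] = adv["coord_loss"]
            traces["subject"][step] = adv["subject_loss"]

        if not np.isfinite(con_loss):
            raise FloatingPointError(
                f"non-finite contrastive loss at step {step}; aborting"
            )
        traces["contrastive"][step] = con_loss

    encoder.dropout = 0.0  # inference: dropout disabled, encoder frozen
    return EmbedderState(
        encoder=encoder,
        bin_edges=edges,
        config=config,
        loss_traces=traces,
        seed=config.seed,
    )


def train_embedder(table: pd.DataFrame, config: EncoderConfig) -> EmbedderState:
    """Train the embedder on a preprocessed voxel table (training subjects only)."""
    fcols = feature_columns(table)
    cfg = config
    if cfg.input_dim != len(fcols):
        cfg = replace(cfg, input_dim=len(fcols))
    state = train_embedder_arrays(
        table[fcols].to_numpy(),
        table[["x", "y", "z"]].to_numpy(),
        table["subject_id"].to_numpy(),
        cfg,
    )
    state.feature_cols = tuple(fcols)
    return state


def encode(state: EmbedderState, features: np.ndarray) -> np.ndarray:
    """Embed feature vectors with the frozen encoder (deterministic)."""
    features = np.asarray(features)
    if features.ndim != 2 or features.shape[1] != state.encoder.input_dim:
        raise ValueError(
            f"feature dimension {features.shape[1:]} != encoder input "
            f"{state.encoder.input_dim}"
        )
    # run inference in the parameters' own dtype, return float64
    z, _ = state.encoder.forward(
        features.astype(state.encoder.params["W0"].dtype), train=False
    )
    z = z.astype(np.float64)
    return z / np.linalg.norm(z, axis=1, keepdims=True)


def encode_table(state: EmbedderState, table: pd.DataFrame) -> np.ndarray:
    cols = state.feature_cols or tuple(feature_columns(table))
    return encode(state, table[list(cols)].to_numpy())


def traces_to_tsv(state: EmbedderState, path) -> None:
    """Write the per-step loss traces as TSV (step, contrastive, coordinate, subject)."""
    df = pd.DataFrame(
        {"step": np.arange(len(state.loss_traces["contrastive"])), **state.loss_traces}
    )
    df.to_csv(path, sep="\t", index=False)


# -- serialization ---------------------------------------------------------


def save_state(state: EmbedderState, path) -> None:
    """Serialize an EmbedderState to a single ``.npz`` checkpoint."""
    meta = {
        "config": _config_to_dict(state.config),
        "feature_cols": list(state.feature_cols) if state.feature_cols else None,
        "seed": state.seed,
        "encoder": {
            "input_dim": state.encoder.input_dim,
            "hidden": list(state.encoder.hidden),
            "output_dim": state.encoder.output_dim,
            "block_order": state.encoder.block_order,
            "l2_normalize_output": state.encoder.l2_normalize_output,
        },
    }
    arrays = {f"param_{k}": v for k, v in state.encoder.params.items()}
    arrays["bin_edges"] = state.bin_edges
    for k, v in state.loss_traces.items():
        arrays[f"trace_{k}"] = v
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_state(path) -> EmbedderState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        enc_meta = meta["encoder"]
        encoder = MLP(
            enc_meta["input_dim"],
            tuple(enc_meta["hidden"]),
            enc_meta["output_dim"],
            block_order=enc_meta["block_order"],
            dropout=0.0,
            l2_normalize_output=enc_meta["l2_normalize_output"],
        )
        encoder.params = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
        traces = {
            k[len("trace_"):]: data[k] for k in data.files if k.startswith("trace_")
        }
        cfg_dict = meta["config"]
        cfg_dict["hidden"] = tuple(cfg_dict["hidden"])
        cfg_dict["head_hidden"] = tuple(cfg_dict["head_hidden"])
        from .config import AugmentationConfig

        cfg_dict["augmentation"] = AugmentationConfig(**cfg_dict["augmentation"])
        config = EncoderConfig(**cfg_dict)
        return EmbedderState(
            encoder=encoder,
            bin_edges=data["bin_edges"],
            config=config,
            loss_traces=traces,
            feature_cols=tuple(meta["feature_cols"]) if meta["feature_cols"] else None,
            seed=meta["seed"],
        )


def _config_to_dict(config: EncoderConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["hidden"] = list(d["hidden"])
    d["head_hidden"] = list(d["head_hidden"])
    return d
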