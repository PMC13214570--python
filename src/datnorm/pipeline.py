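"""Leave-one-HC-out cross-validation, ablations, and fold aggregation.

Each fold holds out one healthy control; all patients are excluded from
training in every fold.  The embedder is trained on the remaining HCs'
voxels only (coordinate-bin edges included), the regressor on those same
HCs' embeddings, and predictions are emitted for the held-out HC and every
PD subject.  PD predictions are aggregated across folds by mean and median;
each HC is predicted only by its own fold.  Every fold carries a manifest of
the subjects actually used for training so leakage can be audited on
artifacts rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .config import EncoderConfig, RegressorConfig
from .embedder import EmbedderState, encode_table, train_embedder
from .evaluate import ROCResult, group_stats, roc_analysis, summarize_roi
from .preprocess import preprocess_table, standardize_atlas
from .regressor import RegressorState, predict_dat, train_regressor
from .synthetic import feature_columns

__all__ = [
    "FoldPlan",
    "FoldPrediction",
    "AggregatedPredictions",
    "PipelineResult",
    "make_folds",
    "run_fold",
    "aggregate_predictions",
    "run_pipeline",
    "run_ablation",
    "audit_folds",
]

Mode = Literal["main", "raw", "no_adversarial"]

_META_COLS = ["subject_id", "group", "age", "young_hc", "x", "y", "z", "roi"]


@dataclass(frozen=True)
class FoldPlan:
    fold_index: int
    train_hc: tuple[str, ...]
    held_out_hc: str
    pd_ids: tuple[str, ...]
    seed: int


@dataclass
class FoldPrediction:
    fold_index: int
    predictions: pd.DataFrame  # held-out HC + all PD, one row per voxel
    manifest: dict
    embedder_state: EmbedderState | None = None
    regressor_state: RegressorState | None = None


@dataclass
class AggregatedPredictions:
    """Fold-aggregated voxel predictions.

    ``table`` holds one row per (subject, voxel) with both ``prediction_mean``
    and ``prediction_median`` columns; for HCs the two coincide (each HC is
    predicted by exactly one fold — its own).
    """

    table: pd.DataFrame
    methods: tuple[str, ...] = ("mean", "median")


@dataclass
class PipelineResult:
    folds: list[FoldPrediction]
    aggregated: AggregatedPredictions
    summary_mean: pd.DataFrame  # ROI summaries of mean-aggregated predictions
    summary_median: pd.DataFrame
    stats_mean: pd.DataFrame
    stats_median: pd.DataFrame
    roc_mean: ROCResult
    roc_median: ROCResult
    mode: str


def _fold_seed(global_seed: int, fold_index: int) -> int:
    return int(
        np.random.SeedSequence([global_seed, fold_index]).generate_state(1)[0]
        % (2**31)
    )


def make_folds(table: pd.DataFrame, global_seed: int = 0) -> list[FoldPlan]:
    """One fold per HC, ordered by subject ID; PD subjects are always test."""
    subjects = table[["subject_id", "group"]].drop_duplicates()
    hcs = sorted(subjects.loc[subjects["group"] == "HC", "subject_id"])
    pds = tuple(sorted(subjects.loc[subjects["group"] == "PD", "subject_id"]))
    if len(hcs) < 3:
        raise ValueError(f"leave-one-HC-out needs at least 3 HCs, got {len(hcs)}")
    return [
        FoldPlan(
            fold_index=k,
            train_hc=tuple(h for h in hcs if h != held_out),
            held_out_hc=held_out,
            pd_ids=pds,
            seed=_fold_seed(global_seed, k),
        )
        for k, held_out in enumerate(hcs)
    ]


def run_fold(
    plan: FoldPlan,
    table: pd.DataFrame,
    encoder_config: EncoderConfig,
    regressor_config: RegressorConfig,
    mode: Mode = "main",
    keep_states: bool = False,
) -> FoldPrediction:
    """Train one fold and predict the held-out HC and all PD subjects.

    ``table`` must already be preprocessed per subject (detrended and
    z-scored; both are subject-wise operations and leak nothing across
    subjects).  ``mode="raw"`` trains the regressor directly on the
    preprocessed features with no embedder; ``mode="no_adversarial"`` trains
    the embedder with the adversarial weights set to zero.
    """
    if mode not in ("main", "raw", "no_adversarial"):
        raise ValueError(f"unknown mode {mode!r}")
    train_tbl = table[table["subject_id"].isin(plan.train_hc)]
    test_ids = [plan.held_out_hc, *plan.pd_ids]
    test_tbl = table[table["subject_id"].isin(test_ids)]
    fcols = feature_columns(table)

    _, atlas_scaler = standardize_atlas(train_tbl["atlas"].to_numpy())
    targets = atlas_scaler.transform(train_tbl["atlas"].to_numpy())

    embedder_state: EmbedderState | None = None
    try:
        enc_cfg = replace(encoder_config, seed=plan.seed, input_dim=len(fcols))
        reg_cfg = replace(regressor_config, seed=plan.seed)
        if mode == "raw":
            reg_cfg = replace(reg_cfg, input_dim=len(fcols))
            train_in = train_tbl[fcols].to_numpy()
            test_in = test_tbl[fcols].to_numpy()
        else:
            if mode == "no_adversarial":
                enc_cfg = replace(enc_cfg, w_coord=0.0, w_subject=0.0)
            embedder_state = train_embedder(train_tbl, enc_cfg)
            reg_cfg = replace(reg_cfg, input_dim=enc_cfg.embed_dim)
            train_in = encode_table(embedder_state, train_tbl)
            test_in = encode_table(embedder_state, test_tbl)
        regressor_state = train_regressor(train_in, targets, reg_cfg)
        preds = predict_dat(regressor_state, test_in, atlas_scaler)
    except Exception as err:
        raise RuntimeError(
            f"fold {plan.fold_index} (held-out {plan.held_out_hc}) failed"
        ) from err

    out = test_tbl[_META_COLS].copy().reset_index(drop=True)
    out["prediction"] = preds
    manifest = {
        "fold_index": plan.fold_index,
        "mode": mode,
        "seed": plan.seed,
        "train_subjects": sorted(train_tbl["subject_id"].unique()),
        "test_subjects": sorted(test_tbl["subject_id"].unique()),
        "held_out_hc": plan.held_out_hc,
        "n_train_voxels": int(len(train_tbl)),
    }
    return FoldPrediction(
        fold_index=plan.fold_index,
        predictions=out,
        manifest=manifest,
        embedder_state=embedder_state if keep_states else None,
        regressor_state=regressor_state if keep_states else None,
    )


def aggregate_predictions(
    folds: list[FoldPrediction], methods: tuple[str, ...] = ("mean", "median")
) -> AggregatedPredictions:
    """Aggregate PD predictions across folds; pass HC predictions through.

    Voxels are matched across folds by (subject, x, y, z).  Both the mean
    and the median aggregate are stored.
    """
    if not folds:
        raise ValueError("no folds to aggregate")
    indices = {f.fold_index for f in folds}
    if indices != set(range(len(folds))):
        missing = sorted(set(range(max(indices) + 1)) - indices)
        raise ValueError(f"missing fold(s): {missing}")
    for m in methods:
        if m not in ("mean", "median"):
            raise ValueError(f"unknown aggregation method {m!r}")

    all_preds = pd.concat(
        [f.predictions.assign(fold=f.fold_index) for f in folds], ignore_index=True
    )
    hc = all_preds[all_preds["group"] == "HC"].copy()
    hc["prediction_mean"] = hc["prediction"]
    hc["prediction_median"] = hc["prediction"]
    hc = hc.drop(columns=["prediction", "fold"])

    pd_rows = all_preds[all_preds["group"] == "PD"]
    key = ["subject_id", "x", "y", "z"]
    agg = pd_rows.groupby(key, sort=False).agg(
        prediction_mean=("prediction", "mean"),
        prediction_median=("prediction", "median"),
    )
    meta = pd_rows.drop_duplicates(subset=key).set_index(key)[
        [c for c in _META_COLS if c not in key]
    ]
    pd_agg = meta.join(agg).reset_index()

    table = pd.concat([hc, pd_agg[hc.columns]], ignore_index=True)
    return AggregatedPredictions(table=table, methods=methods)


def audit_folds(folds: list[FoldPrediction]) -> None:
    """Assert on the serialized manifests that no fold trained on test data."""
    for f in folds:
        m = f.manifest
        train = set(m["train_subjects"])
        forbidden = {m["held_out_hc"]} | {
            s for s in m["test_subjects"] if s.startswith("PD")
        }
        overlap = train & forbidden
        if overlap:
            raise AssertionError(
                f"fold {m['fold_index']}: training set leaks test subjects {sorted(overlap)}"
            )
        test_groups = set(m["test_subjects"])
        if m["held_out_hc"] not in test_groups:
            raise AssertionError(
                f"fold {m['fold_index']}: held-out HC missing from test set"
            )


def run_pipeline(
    table: pd.DataFrame,
    encoder_config: EncoderConfig,
    regressor_config: RegressorConfig,
    global_seed: int = 0,
    mode: Mode = "main",
    preprocess: bool = True,
    roc_roi: str = "putamen",
    stats_rois: tuple[str, ...] = ("putamen", "caudate", "striatum"),
) -> PipelineResult:
    """Full pipeline: preprocessing → leave-one-HC-out folds → aggregation → stats.

    ROI summaries cover every labeled ROI (plus the striatum union);
    ``stats_rois`` selects the ROIs entering the group tests (and the BH
    correction family).
    """
    if preprocess:
        table, _ = preprocess_table(table)
    plans = make_folds(table, global_seed)
    folds = [
        run_fold(plan, table, encoder_config, regressor_config, mode=mode)
        for plan in plans
    ]
    audit_folds(folds)
    aggregated = aggregate_predictions(folds)

    summary_rois = tuple(
        sorted(set(aggregated.table["roi"]) - {"background"})
    ) + ("striatum",)
    results: dict[str, dict] = {}
    for method in ("mean", "median"):
        summary = summarize_roi(
            aggregated.table, rois=summary_rois, value_col=f"prediction_{method}"
        )
        stats_tbl = group_stats(
            summary, value_col="summary_mean", rois=stats_rois, seed=global_seed
        )
        sub = summary[summary["roi"] == roc_roi]
        roc = roc_analysis(
            sub.loc[sub["group"] == "HC", "summary_mean"].to_numpy(),
            sub.loc[sub["group"] == "PD", "summary_mean"].to_numpy(),
        )
        results[method] = {"summary": summary, "stats": stats_tbl, "roc": roc}

    return PipelineResult(
        folds=folds,
        aggregated=aggregated,
        summary_mean=results["mean"]["summary"],
        summary_median=results["median"]["summary"],
        stats_mean=results["mean"]["stats"],
        stats_median=results["median"]["stats"],
        roc_mean=results["mean"]["roc"],
        roc_median=results["median"]["roc"],
        mode=mode,
    )


def run_ablation(
    table: pd.DataFrame,
    mode: Mode,
    encoder_config: EncoderConfig,
    regressor_config: RegressorConfig,
    global_seed: int = 0,
) -> PipelineResult:
    """Run an ablated pipeline: ``raw`` (no embedder) or ``no_adversarial``."""
    if mode not in ("raw", "no_adversarial"):
        raise ValueError(f"unknown ablation mode {mode!r}")
    return run_pipeline(
        table, encoder_config, regressor_config, global_seed=global_seed, mode=mode
    )
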