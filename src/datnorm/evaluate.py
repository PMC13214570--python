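"""ROI summaries, group statistics and ROC analysis of DaT predictions.

Subject-level predictions are summarized as ROI means/medians (striatum =
union of putamen and caudate voxels), compared between groups with
two-sided Welch's t-tests, corrected across ROIs with Benjamini–Hochberg,
and effect sizes reported as Hedges' g with 95% confidence intervals
(seeded percentile bootstrap by default, Wald as an alternative).
Diagnostic utility is assessed by ROC analysis with HC as the negative and
PD as the positive class; because dopaminergic deficit lowers predicted
binding, the score is the negated ROI summary, and the Youden-optimal
threshold is reported back on the binding-potential scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ROCResult",
    "linear_subject_probe",
    "summarize_roi",
    "welch_t",
    "bh_fdr",
    "hedges_g",
    "roc_analysis",
    "group_stats",
    "age_restricted",
    "correlation_controls",
]

logger = logging.getLogger(__name__)

STRIATAL_ROIS = ("putamen", "caudate")


def linear_subject_probe(
    embeddings: np.ndarray,
    subject_labels: np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.5,
) -> float:
    """Held-out accuracy of a post-hoc linear probe for subject identity.

    Fits a multinomial logistic regression on half the voxels (stratified by
    subject) and scores the other half.  On embeddings that successfully
    hide subject identity this stays near chance (1 / n_subjects); on
    subject-biased embeddings it rises well above.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    labels = np.asarray(subject_labels)
    zt, zv, yt, yv = train_test_split(
        np.asarray(embeddings), labels, test_size=test_fraction,
        stratify=labels, random_state=seed,
    )
    probe = LogisticRegression(max_iter=500).fit(zt, yt)
    return float(probe.score(zv, yv))


def summarize_roi(
    predictions: pd.DataFrame,
    rois: tuple[str, ...] = ("putamen", "caudate", "striatum"),
    value_col: str = "prediction",
) -> pd.DataFrame:
    """Per-subject, per-ROI mean and median of voxel predictions.

    ``predictions`` is a long table with ``subject_id``, ``group``, ``age``,
    ``roi`` and a prediction column.  The striatum summary is computed over
    the union of putamen and caudate voxels (voxel-weighted, not a mean of
    ROI means).  Subjects with an empty ROI are logged and omitted for that
    ROI.
    """
    rows = []
    meta_cols = [c for c in ("group", "age", "young_hc") if c in predictions.columns]
    for sid, sub in predictions.groupby("subject_id", sort=True):
        meta = {c: sub[c].iloc[0] for c in meta_cols}
        for roi in rois:
            if roi == "striatum":
                vals = sub.loc[sub["roi"].isin(STRIATAL_ROIS), value_col]
            else:
                vals = sub.loc[sub["roi"] == roi, value_col]
            if len(vals) == 0:
                logger.warning("subject %s has no voxels in ROI %s; skipped", sid, roi)
                continue
            rows.append(
                {
                    "subject_id": sid,
                    **meta,
                    "roi": roi,
                    "summary_mean": float(vals.mean()),
                    "summary_median": float(vals.median()),
                    "n_voxels": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch's t-test; returns (t, p, Welch–Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hedges_g(
    a: np.ndarray,
    b: np.ndarray,
    ci: str = "bootstrap",
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Hedges' g for a − b with a 95% confidence interval.

    g is Cohen's d with pooled standard deviation (df = n1 + n2 − 2) times
    the small-sample correction J = 1 − 3 / (4·df − 1).  The CI is a seeded
    percentile bootstrap by default (``ci="bootstrap"``) or the analytic
    normal approximation (``ci="wald"``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    g = _g_point(a, b)
    if ci == "bootstrap":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
        ra = a[rng.integers(0, n1, (n_boot, n1))]
        rb = b[rng.integers(0, n2, (n_boot, n2))]
        df = n1 + n2 - 2
        pooled = (
            (n1 - 1) * ra.var(axis=1, ddof=1) + (n2 - 1) * rb.var(axis=1, ddof=1)
        ) / df
        diff = ra.mean(axis=1) - rb.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            draws = diff / np.sqrt(pooled) * (1.0 - 3.0 / (4.0 * df - 1.0))
        draws[pooled == 0] = 0.0  # degenerate resample: no detectable effect
        lo, hi = np.percentile(draws, [2.5, 97.5])
    elif ci == "wald":
        se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2 * (n1 + n2 - 2)))
        lo, hi = g - 1.959963984540054 * se, g + 1.959963984540054 * se
    else:
        raise ValueError(f"unknown CI method {ci!r}")
    return float(g), float(lo), float(hi)


def _g_point(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        raise ZeroDivisionError("zero pooled variance")
    d = (a.mean() - b.mean()) / np.sqrt(pooled)
    return d * (1.0 - 3.0 / (4.0 * df - 1.0))


@dataclass(frozen=True)
class ROCResult:
    """ROC analysis of ROI summaries with the deficit-oriented (flipped) score."""

    auc: float
    threshold: float  # Youden-optimal, on the binding-potential scale
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    flipped: bool
    fpr: np.ndarray  # curve points, sorted by threshold sweep
    tpr: np.ndarray


def roc_analysis(
    hc_summaries: np.ndarray, pd_summaries: np.ndarray, flip: bool = True
) -> ROCResult:
    """ROC for PD-vs-HC separation of ROI summaries.

    HCs are the negative class, PD the positive class.  With ``flip=True``
    (default) the classification score is the *negated* summary — lower
    predicted binding is more PD-like — so AUC exceeds 0.5 when PD
    predictions are lower.  Thresholds are scanned at midpoints between
    consecutive distinct scores; the operating point maximizes the Youden
    index (sensitivity + specificity − 1), ties broken toward higher
    specificity; the threshold is reported on the binding-potential scale.
    """
    hc = np.asarray(hc_summaries, dtype=float)
    pd_ = np.asarray(pd_summaries, dtype=float)
    if len(hc) == 0 or len(pd_) == 0:
        raise ValueError("both groups must be non-empty")
    sign = -1.0 if flip else 1.0
    neg = sign * hc  # negative-class scores
    pos = sign * pd_  # positive-class scores

    distinct = np.unique(np.concatenate([neg, pos]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    # classify positive when score >= threshold
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    order = np.lexsort((tpr, fpr))  # proper curve: tpr ascending within ties
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    sens = tpr
    spec = 1.0 - fpr
    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    best_i = best[np.argmax(spec[best])]
    thr_score = float(thresholds[best_i])
    return ROCResult(
        auc=auc,
        threshold=sign * thr_score,
        sensitivity=float(sens[best_i]),
        specificity=float(spec[best_i]),
        balanced_accuracy=float((sens[best_i] + spec[best_i]) / 2.0),
        flipped=flip,
        fpr=fpr[order],
        tpr=tpr[order],
    )


def group_stats(
    summary: pd.DataFrame,
    value_col: str = "summary_mean",
    rois: tuple[str, ...] = ("putamen", "caudate", "striatum"),
    ci: str = "bootstrap",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-ROI Welch t, BH-FDR q across the tested ROIs, Hedges' g with CI.

    The t statistic and g are oriented HC − PD, so a dopaminergic deficit in
    PD yields positive values, matching the reporting convention for
    normative deviations.
    """
    rows = []
    for roi in rois:
        sub = summary[summary["roi"] == roi]
        hc = sub.loc[sub["group"] == "HC", value_col].to_numpy()
        pd_ = sub.loc[sub["group"] == "PD", value_col].to_numpy()
        t, p, df = welch_t(hc, pd_)
        g, lo, hi = hedges_g(hc, pd_, ci=ci, seed=seed)
        rows.append(
            {
                "roi": roi,
                "t": t,
                "p": p,
                "df": df,
                "hedges_g": g,
                "g_ci_low": lo,
                "g_ci_high": hi,
                "n_hc": len(hc),
                "n_pd": len(pd_),
            }
        )
    out = pd.DataFrame(rows)
    out.insert(3, "q", bh_fdr(out["p"].to_numpy()))
    return out


def age_restricted(
    summary: pd.DataFrame,
    min_hc_age: float,
    value_col: str = "summary_mean",
    roc_roi: str = "putamen",
    ci: str = "bootstrap",
    seed: int = 0,
) -> tuple[pd.DataFrame, ROCResult]:
    """Re-run group statistics after excluding HCs younger than ``min_hc_age``.

    Predictions are reused — nothing is retrained; only the HC sample
    entering the statistics changes.
    """
    keep = (summary["group"] != "HC") | (summary["age"] >= min_hc_age)
    filtered = summary[keep]
    n_hc = filtered.loc[filtered["roi"] == roc_roi, "group"].eq("HC").sum()
    if n_hc < 2:
        raise ValueError(
            f"age filter at {min_hc_age} leaves {n_hc} HC(s); need at least 2"
        )
    stats_tbl = group_stats(filtered, value_col=value_col, ci=ci, seed=seed)
    sub = filtered[filtered["roi"] == roc_roi]
    roc = roc_analysis(
        sub.loc[sub["group"] == "HC", value_col].to_numpy(),
        sub.loc[sub["group"] == "PD", value_col].to_numpy(),
    )
    return stats_tbl, roc


def correlation_controls(
    summary: pd.DataFrame,
    covariate: str,
    roi: str = "putamen",
    value_col: str = "summary_mean",
) -> tuple[float, float]:
    """Pearson correlation of ROI summaries with a per-subject covariate."""
    sub = summary[summary["roi"] == roi]
    x = sub[covariate].to_numpy(dtype=float)
    y = sub[value_col].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError(f"constant covariate {covariate!r}")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
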