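"""Statistical machinery: ROI summaries, Welch/BH/Hedges, ROC/Youden."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from datnorm.evaluate import (
    age_restricted,
    bh_fdr,
    correlation_controls,
    group_stats,
    hedges_g,
    roc_analysis,
    summarize_roi,
    welch_t,
)


def _pred_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "group", "age", "roi", "prediction"])


class TestSummarizeROI:
    def test_hand_computed_mean_and_median(self):
        df = _pred_frame(
            [("s1", "HC", 60, "putamen", v) for v in (1.0, 2.0, 3.0)]
            + [("s1", "HC", 60, "caudate", v) for v in (1.0, 2.0, 10.0)]
        )
        out = summarize_roi(df, rois=("putamen", "caudate"))
        put = out[out["roi"] == "putamen"].iloc[0]
        caud = out[out["roi"] == "caudate"].iloc[0]
        assert put["summary_mean"] == 2.0 and put["summary_median"] == 2.0
        assert caud["summary_mean"] == pytest.approx(13 / 3)
        assert caud["summary_median"] == 2.0

    def test_striatum_is_voxel_weighted_union(self):
        df = _pred_frame(
            [("s1", "HC", 60, "putamen", 1.0), ("s1", "HC", 60, "putamen", 1.0),
             ("s1", "HC", 60, "caudate", 3.0)]
        )
        out = summarize_roi(df, rois=("striatum",))
        assert out.iloc[0]["summary_mean"] == pytest.approx(5 / 3)

    def test_empty_roi_skipped(self):
        df = _pred_frame([("s1", "HC", 60, "putamen", 1.0),
                          ("s1", "HC", 60, "putamen", 2.0)])
        out = summarize_roi(df, rois=("putamen", "caudate"))
        assert set(out["roi"]) == {"putamen"}


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        t, p, df = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        t, p, df = welch_t(a, b)
        # textbook computation
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_exp = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_exp = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_exp = 2 * sps.t.sf(abs(t_exp), df_exp)
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert df == pytest.approx(df_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_antisymmetric_in_samples(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 7)
        t1, p1, _ = welch_t(a, b)
        t2, p2, _ = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_tiny_sample_raises(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def _bh_bruteforce(p):
    """Independent step-up oracle: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            np.testing.assert_allclose(bh_fdr(p), _bh_bruteforce(p), atol=1e-12)

    def test_q_dominates_p_and_is_rank_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 50)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestHedges:
    def test_small_sample_correction_factor(self):
        # n1 = n2 = 10 -> df = 18 -> J = 1 - 3/71
        rng = np.random.default_rng(3)
        a = rng.normal(1, 1, 10)
        b = rng.normal(0, 1, 10)
        g, _, _ = hedges_g(a, b, ci="wald")
        df = 18
        pooled = (9 * a.var(ddof=1) + 9 * b.var(ddof=1)) / df
        d = (a.mean() - b.mean()) / np.sqrt(pooled)
        assert (1 - 3 / 71) == pytest.approx(0.957746, abs=1e-6)
        assert g == pytest.approx(d * (1 - 3 / 71), abs=1e-12)

    def test_equal_means_ci_straddles_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        g, lo, hi = hedges_g(x, x.copy(), seed=0)
        assert g == 0.0
        assert lo <= 0.0 <= hi

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 1, 12), rng.normal(0, 1, 9)
        g1, _, _ = hedges_g(a, b, ci="wald")
        g2, _, _ = hedges_g(2 * a, 2 * b, ci="wald")
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_bootstrap_ci_contains_g_and_is_seeded(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(1.0, 1, 10), rng.normal(0, 1, 8)
        g, lo, hi = hedges_g(a, b, seed=7)
        g2, lo2, hi2 = hedges_g(a, b, seed=7)
        assert (lo, hi) == (lo2, hi2)
        assert lo <= g <= hi

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            hedges_g(np.full(5, 1.0), np.full(5, 2.0), ci="wald")


def _auc_pairwise(neg_scores, pos_scores):
    """Oracle: Mann–Whitney pairwise wins + half-credit ties."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(neg_scores) * len(pos_scores))


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis(np.array([3.0, 4.0]), np.array([1.0, 2.0]))
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.balanced_accuracy == 1.0
        # threshold lies between the groups, on the binding-potential scale
        assert 2.0 < r.threshold < 3.0

    def test_exchangeable_groups_give_half(self):
        r = roc_analysis(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert r.auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            hc = np.round(rng.normal(2, 1, rng.integers(2, 9)), 1)
            pd_ = np.round(rng.normal(1.5, 1, rng.integers(2, 9)), 1)
            r = roc_analysis(hc, pd_)
            assert r.auc == pytest.approx(_auc_pairwise(-hc, -pd_), abs=1e-12)

    def test_balanced_accuracy_identity_along_curve(self):
        rng = np.random.default_rng(8)
        hc, pd_ = rng.normal(2, 1, 12), rng.normal(1, 1, 9)
        r = roc_analysis(hc, pd_)
        # identity (sens + spec)/2 holds at every scanned point of the curve
        np.testing.assert_allclose(
            (r.tpr + (1 - r.fpr)) / 2.0,
            r.tpr / 2 + (1 - r.fpr) / 2,
            atol=1e-15,
        )
        assert r.balanced_accuracy == pytest.approx(
            (r.sensitivity + r.specificity) / 2, abs=1e-15
        )

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        hc, pd_ = rng.normal(2, 1, 15), rng.normal(1.2, 1, 10)
        r = roc_analysis(hc, pd_)
        y = np.r_[np.zeros(15), np.ones(10)]
        scores = np.r_[-hc, -pd_]
        assert r.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_youden_threshold_ties_break_toward_specificity(self):
        # two thresholds tie on Youden: pick the one with higher specificity
        hc = np.array([3.0, 4.0, 5.0, 2.0])
        pd_ = np.array([1.0, 2.5, 4.5, 0.5])
        r = roc_analysis(hc, pd_)
        j = r.sensitivity + r.specificity - 1
        # recompute all operating points from the curve, assert optimality
        js = r.tpr + (1 - r.fpr) - 1
        assert j == pytest.approx(js.max(), abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            roc_analysis(np.array([]), np.array([1.0]))


class TestGroupLevel:
    @pytest.fixture()
    def summary(self):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(10):
            grp = "HC" if i < 6 else "PD"
            age = 60.0 + rng.normal(0, 5) if grp == "PD" or i >= 2 else 25.0
            shift = 0.0 if grp == "HC" else -0.8
            for roi in ("putamen", "caudate", "striatum"):
                rows.append({
                    "subject_id": f"s{i}", "group": grp, "age": age, "roi": roi,
                    "summary_mean": rng.normal(2 + shift * (roi != "caudate"), 0.3),
                })
        return pd.DataFrame(rows)

    def test_group_stats_q_dominates_p(self, summary):
        out = group_stats(summary, ci="wald")
        assert (out["q"] >= out["p"] - 1e-15).all()
        assert set(out["roi"]) == {"putamen", "caudate", "striatum"}
        assert ((out["g_ci_low"] <= out["hedges_g"]) & (out["hedges_g"] <= out["g_ci_high"])).all()

    def test_age_filter_retaining_all_is_identity(self, summary):
        full = group_stats(summary, ci="wald")
        filt, _ = age_restricted(summary, min_hc_age=0.0, ci="wald")
        pd.testing.assert_frame_equal(full, filt)

    def test_age_filter_bookkeeping(self, summary):
        n_young = (
            summary[(summary["roi"] == "putamen") & (summary["group"] == "HC")]["age"]
            < 40
        ).sum()
        filt, roc = age_restricted(summary, min_hc_age=40.0, ci="wald")
        n_before = group_stats(summary, ci="wald")["n_hc"].iloc[0]
        assert filt["n_hc"].iloc[0] == n_before - n_young

    def test_overaggressive_age_filter_raises(self, summary):
        with pytest.raises(ValueError, match="need at least 2"):
            age_restricted(summary, min_hc_age=200.0)

    def test_correlation_controls_sign_cases(self, summary):
        put = summary[summary["roi"] == "putamen"].copy()
        put["cov_same"] = put["summary_mean"]
        put["cov_anti"] = -put["summary_mean"]
        r, _ = correlation_controls(put, "cov_same")
        assert r == pytest.approx(1.0)
        r, _ = correlation_controls(put, "cov_anti")
        assert r == pytest.approx(-1.0)
        put["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            correlation_controls(put, "const")

    def test_null_covariate_correlation_is_small_over_seeds(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(50):
            df = pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(20)],
                "group": "HC", "roi": "putamen",
                "age": rng.uniform(20, 70, 20),
                "summary_mean": rng.normal(2, 0.5, 20),
            })
            ps.append(correlation_controls(df, "age")[1])
        # under independence p-values are uniform: mean near 0.5
        assert 0.3 < np.mean(ps) < 0.7


def test_age_restriction_preserves_age_neutral_effect_over_seeds():
    """When the planted group effect is independent of age, filtering out
    young HCs changes Hedges' g only by sampling noise (|dg| < 0.5)."""
    from datnorm.evaluate import age_restricted, group_stats

    deltas = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(14):
            grp = "HC" if i < 9 else "PD"
            age = rng.uniform(22, 69) if grp == "HC" else rng.uniform(48, 73)
            shift = -0.6 if grp == "PD" else 0.0
            for roi in ("putamen", "caudate", "striatum"):
                rows.append({
                    "subject_id": f"s{i}", "group": grp, "age": age, "roi": roi,
                    "summary_mean": rng.normal(2.0 + shift, 0.3),
                })
        summary = pd.DataFrame(rows)
        full = group_stats(summary, ci="wald")
        filt, _ = age_restricted(summary, min_hc_age=40.0, ci="wald")
        g_full = full.loc[full["roi"] == "putamen", "hedges_g"].iloc[0]
        g_filt = filt.loc[filt["roi"] == "putamen", "hedges_g"].iloc[0]
        deltas.append(abs(g_full - g_filt))
    assert np.mean(deltas) < 0.5
    assert np.median(deltas) < 0.5


class TestPropertyBased:
    """Randomized invariants (derandomized hypothesis search)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=16))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_bh_dominates_p_and_matches_stepup_oracle(self, p):
        q = bh_fdr(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        np.testing.assert_allclose(q, _bh_bruteforce(p), atol=1e-10)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=10),
        st.lists(st.floats(-50, 50), min_size=1, max_size=10),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_auc_equals_pairwise_count_and_stays_in_range(self, hc, pd_):
        r = roc_analysis(np.asarray(hc), np.asarray(pd_))
        assert 0.0 <= r.auc <= 1.0
        assert r.auc == pytest.approx(
            _auc_pairwise([-h for h in hc], [-p for p in pd_]), abs=1e-9
        )
        assert r.balanced_accuracy == pytest.approx(
            (r.sensitivity + r.specificity) / 2.0, abs=1e-12
        )
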