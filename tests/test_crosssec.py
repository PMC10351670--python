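import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hippotex.crosssec import (AmyloidConfig, classify_amyloid,
                               exclude_outliers, GroupModel,
                               pairwise_contrasts, cohens_d, cohens_f,
                               adjust_pvalues)
from hippotex.simulate import simulate_baseline_table


# ---------------------------------------------------------------------------
# amyloid classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("csf,expected", [
    (900.0, "positive"),            # below threshold, outside the 5% band
    (1000.0, "excluded_borderline"),  # inside [931, 1029]
    (931.0, "excluded_borderline"),
    (1100.0, "negative"),
])
def test_csf_rule(csf, expected):
    assert classify_amyloid(csf_ab42=csf) == expected


def test_pet_rule_when_csf_missing():
    cfg = AmyloidConfig(centiloid_threshold=24.0)
    assert classify_amyloid(centiloid=50.0, config=cfg) == "positive"
    assert classify_amyloid(centiloid=5.0, config=cfg) == "negative"
    # within 5% of 24 -> borderline
    assert classify_amyloid(centiloid=24.5, config=cfg) == "excluded_borderline"


def test_csf_takes_precedence_over_pet():
    assert classify_amyloid(csf_ab42=1200.0, centiloid=90.0) == "negative"


def test_missing_both_unknown_and_negative_conc_rejected():
    assert classify_amyloid() == "unknown"
    with pytest.raises(ValueError, match="negative"):
        classify_amyloid(csf_ab42=-5.0)


# ---------------------------------------------------------------------------
# outlier fences
# ---------------------------------------------------------------------------

def test_symmetric_data_not_flagged():
    v = np.linspace(-1, 1, 100)
    _, flags = exclude_outliers(v)
    assert flags.sum() == 0


def test_planted_extreme_flagged_by_direct_rule():
    rng = np.random.default_rng(1)
    v = np.r_[rng.normal(size=200), 25.0]
    kept, flags = exclude_outliers(v)
    q1, q3 = np.percentile(v, [25, 75])
    expected = (v < v.mean() - 1.5 * (q3 - q1)) | (v > v.mean() + 1.5 * (q3 - q1))
    np.testing.assert_array_equal(flags, expected)
    assert flags[-1]


def test_constant_vector_keeps_only_exact_mean():
    v = np.array([1.0, 1.0, 1.0, 1.0, 2.0])
    kept, flags = exclude_outliers(v)
    # IQR = 0: the fence collapses to the mean, 1.2; nothing equals it
    assert flags.all()
    v2 = np.ones(5)
    kept2, flags2 = exclude_outliers(v2)
    assert not flags2.any()


def test_quartile_fence_variant():
    v = np.r_[np.linspace(0, 1, 50), 10.0]
    _, f_mean = exclude_outliers(v, fence="mean")
    _, f_q = exclude_outliers(v, fence="quartile")
    assert f_mean[-1] and f_q[-1]


# ---------------------------------------------------------------------------
# effect sizes and Holm
# ---------------------------------------------------------------------------

def test_cohens_d_closed_form():
    x = np.array([0.0, 1.0, -1.0, 0.5, -0.5] * 20)
    y = x + 1.0
    assert cohens_d(y, x) == pytest.approx(1.0 / x.std(ddof=1), rel=1e-12)


def test_cohens_f_half_of_d_for_two_equal_groups():
    a = np.array([0.0, 1.0, -1.0] * 30)
    b = a + 1.0
    vals = np.r_[a, b]
    grp = np.r_[["a"] * len(a), ["b"] * len(b)]
    d = cohens_d(b, a)
    f = cohens_f(vals, grp)
    assert f == pytest.approx(d / 2, rel=0.02)


def test_cohens_f_matches_variance_ratio_formula():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=200)
    grp = np.repeat(list("abcd"), 50)
    vals[50:100] += 0.8
    f = cohens_f(vals, grp)
    df = pd.DataFrame({"v": vals, "g": grp})
    grand = vals.mean()
    between = np.mean([(df[df.g == g].v.mean() - grand) ** 2 for g in "abcd"])
    within = np.mean([df[df.g == g].v.var() for g in "abcd"])
    assert f == pytest.approx(np.sqrt(between / within), rel=1e-10)


def test_holm_closed_form_and_oracle():
    np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03]),
                               [0.03, 0.04, 0.04])
    assert adjust_pvalues([0.2]) == pytest.approx([0.2])
    rng = np.random.default_rng(0)
    p = rng.uniform(size=9)
    # textbook step-down oracle
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    np.testing.assert_allclose(adjust_pvalues(p), adj, atol=1e-12)
    padj = adjust_pvalues(p)
    assert (padj >= p - 1e-15).all()


def test_bh_variant_available():
    p = [0.01, 0.02, 0.03, 0.5]
    bh = adjust_pvalues(p, method="bh")
    assert (np.asarray(bh) >= np.asarray(p)).all()


# ---------------------------------------------------------------------------
# the group model
# ---------------------------------------------------------------------------

def test_group_model_agrees_with_statsmodels_mixedlm():
    df = simulate_baseline_table(n_per_group=60, site_sd=0.8,
                                 group_effect={"ADD-Ab+": 1.0}, seed=2)
    res = GroupModel(df, "y").fit()
    from hippotex.crosssec import _design
    X, _ = _design(df, "group_bl", ["age_bl", "sex", "education", "icv"],
                   "CU-Ab-")
    ref = sm.MixedLM(df["y"].to_numpy(), X.to_numpy(),
                     groups=df["site"]).fit(reml=True)
    np.testing.assert_allclose(res.params.to_numpy(), ref.fe_params, atol=1e-3)
    assert res.site_sd == pytest.approx(
        float(np.sqrt(np.asarray(ref.cov_re)[0, 0])), abs=0.02)


def test_zero_site_variance_estimated_near_zero():
    df = simulate_baseline_table(n_per_group=80, site_sd=0.0, seed=3)
    res = GroupModel(df, "y").fit()
    # estimated site variance is a small fraction of the residual variance
    assert res.site_sd**2 < 0.02 * res.resid_sd**2


def test_rank_deficient_design_lists_aliased_column():
    df = simulate_baseline_table(n_per_group=30, seed=4)
    df["dup"] = df["age_bl"]
    with pytest.raises(ValueError, match="dup"):
        GroupModel(df, "y", covariates=("age_bl", "sex", "education", "icv",
                                        "dup")).fit()


def test_single_group_rejected():
    df = simulate_baseline_table(n_per_group=30, groups=("CU-Ab-",), seed=5)
    with pytest.raises(ValueError, match="2 groups"):
        GroupModel(df, "y")


def test_pairwise_null_d_near_zero():
    df = simulate_baseline_table(n_per_group=400, site_sd=0.0, seed=6)
    pw = pairwise_contrasts(df, "y")
    assert all(abs(c["cohens_d"]) < 0.15 for c in pw)
    assert all(c["p_adjusted"] >= c["p_value"] for c in pw)


def test_pairwise_requires_non_reference_group():
    df = simulate_baseline_table(n_per_group=30, groups=("CU-Ab-",), seed=7)
    with pytest.raises(ValueError):
        pairwise_contrasts(df, "y")


def test_summary_mentions_group_term():
    df = simulate_baseline_table(n_per_group=40, seed=8)
    res = GroupModel(df, "y").fit()
    s = res.summary()
    assert "group" in s and "Cohen's f" in s
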