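import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mssm.group_stats import (
    bh_fdr,
    effect_size_comparison,
    extra_region_correlation,
    percent_significant,
    vertex_ttest,
)

from .oracles import bh_stepup, pooled_ttest


def test_identical_groups_give_null_statistics(rng):
    A = rng.standard_normal((6, 20))
    stat = vertex_ttest(A, A.copy())
    np.testing.assert_allclose(stat.t, 0.0, atol=1e-12)
    np.testing.assert_allclose(stat.p, 1.0, atol=1e-12)
    np.testing.assert_allclose(stat.d, 0.0, atol=1e-12)
    assert not stat.significant.any()


def test_cohens_d_approaches_standardised_mean_difference(rng):
    A = rng.normal(1.0, 1.0, size=(4000, 3))
    B = rng.normal(0.0, 1.0, size=(4000, 3))
    stat = vertex_ttest(A, B)
    np.testing.assert_allclose(stat.d, 1.0, atol=0.1)


def test_ttest_matches_brute_force_formula(rng):
    for _ in range(25):
        na, nb = rng.integers(3, 12, size=2)
        A = rng.normal(size=(na, 5))
        B = rng.normal(size=(nb, 5))
        stat = vertex_ttest(A, B)
        for v in range(5):
            t, p, d = pooled_ttest(A[:, v], B[:, v])
            assert stat.t[v] == pytest.approx(t, abs=1e-10)
            assert stat.p[v] == pytest.approx(p, abs=1e-10)
            assert stat.d[v] == pytest.approx(d, abs=1e-10)


def test_zero_variance_vertex_undefined(rng):
    A = rng.standard_normal((5, 3))
    B = rng.standard_normal((5, 3))
    A[:, 1] = B[:, 1] = 2.0
    stat = vertex_ttest(A, B)
    assert not stat.defined[1]
    assert np.isnan(stat.t[1])


def test_bh_examples():
    assert bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), 0.05).all()
    assert not bh_fdr(np.ones(50), 0.05).any()
    assert bh_fdr(np.array([0.04]), 0.05).all()      # m=1: BH is the raw threshold
    assert bh_fdr(np.array([]), 0.05).size == 0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10**6), q=st.sampled_from([0.01, 0.05, 0.1]))
def test_bh_matches_stepup_definition(seed, q):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, 120))
    p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
    np.testing.assert_array_equal(bh_fdr(p, q), bh_stepup(p, q))


def test_percent_significant_counts_defined_only():
    stat = vertex_ttest(
        np.array([[1.0, 2.0, 5.0]] * 5) + np.random.default_rng(0).normal(0, 0.1, (5, 3)),
        np.array([[1.0, 2.0, 0.0]] * 5) + np.random.default_rng(1).normal(0, 0.1, (5, 3)),
    )
    pct = percent_significant(stat)
    assert 0.0 <= pct <= 100.0
    n_def = stat.defined.sum()
    assert pct == pytest.approx(100.0 * stat.significant.sum() / n_def)


def test_effect_size_comparison_identical_maps(rng):
    A = rng.standard_normal((6, 10))
    B = rng.standard_normal((6, 10))
    stat = vertex_ttest(A, B)
    cmp_ = effect_size_comparison(stat, stat)
    np.testing.assert_allclose(cmp_.d_difference[cmp_.defined], 0.0, atol=1e-12)
    assert not cmp_.multiscale_better.any()


def test_extra_region_score_identical_to_y_gives_perfect_correlation(rng):
    n, nv = 20, 30
    mssm_maps = rng.standard_normal((n, nv))
    ct_maps = rng.standard_normal((n, nv))
    mssm_sig = np.zeros(nv, bool)
    mssm_sig[:10] = True
    ct_sig = np.zeros(nv, bool)
    ct_sig[5:8] = True
    res = extra_region_correlation(
        mssm_maps, ct_maps, scores=mssm_maps[:, mssm_sig & ~ct_sig].mean(axis=1),
        mssm_significant=mssm_sig, ct_significant=ct_sig,
    )
    assert not res.empty
    assert not np.any(res.extra_mask & ct_sig)
    assert res.raw.pearson == pytest.approx(1.0)
    assert res.raw.spearman == pytest.approx(1.0)


def test_partial_matches_raw_when_control_independent():
    # control variable independent of y and the score: partialling barely
    # changes the correlation (mean |difference| < 0.05 at n=60)
    diffs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        n = 60
        y_latent = rng.standard_normal(n)
        maps = y_latent[:, None] + rng.normal(0, 0.5, size=(n, 8))
        score = y_latent + rng.standard_normal(n)
        control_maps = rng.standard_normal((n, 8))   # independent thickness
        res = extra_region_correlation(
            maps, control_maps, score,
            mssm_significant=np.ones(8, bool), ct_significant=np.zeros(8, bool),
        )
        diffs.append(abs(res.partial_x_all.pearson - res.raw.pearson))
    assert np.mean(diffs) < 0.05


def test_partial_correlation_agrees_with_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    n = 50
    y = rng.standard_normal(n)
    score = y + rng.standard_normal(n)
    control = 0.5 * y + rng.standard_normal(n)
    res = extra_region_correlation(
        np.tile(y[:, None], (1, 4)), np.tile(control[:, None], (1, 4)), score,
        mssm_significant=np.ones(4, bool), ct_significant=np.zeros(4, bool),
    )
    df = pd.DataFrame({"y": y, "score": score, "control": control})
    expected = pingouin.partial_corr(df, x="y", y="score", covar="control")
    assert res.partial_x_all.pearson == pytest.approx(float(expected["r"].iloc[0]),
                                                      abs=1e-10)
    expected_s = pingouin.partial_corr(df, x="y", y="score", covar="control",
                                       method="spearman")
    assert res.partial_x_all.spearman == pytest.approx(float(expected_s["r"].iloc[0]),
                                                       abs=1e-10)


def test_generating_coefficient_sign_recovered():
    # score generated from the in-mask signal: the partial correlation must
    # recover a positive association in nearly every repetition
    positive = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 60
        signal = rng.standard_normal(n)
        maps = signal[:, None] + rng.normal(0, 0.4, size=(n, 6))
        thickness = -0.3 * signal[:, None] + rng.normal(0, 1.0, size=(n, 6))
        score = 1.5 * signal + rng.standard_normal(n)
        res = extra_region_correlation(
            maps, thickness, score,
            mssm_significant=np.ones(6, bool), ct_significant=np.zeros(6, bool),
        )
        if res.partial_x_all.pearson > 0:
            positive += 1
    assert positive >= 0.95 * n_seeds


def test_empty_extra_region_is_explicit():
    res = extra_region_correlation(
        np.zeros((5, 4)), np.zeros((5, 4)), np.arange(5.0),
        mssm_significant=np.zeros(4, bool), ct_significant=np.zeros(4, bool),
    )
    assert res.empty
    assert res.raw is None
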