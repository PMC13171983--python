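"""Scaling, PCA, Welch tests, BH-FDR, top-k, RT-logD regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ccmscan.stats import (bh_adjust, differential, minmax_scale, pca,
                           rt_logd_fit, top_k, welch_t)


def test_minmax_scale_basic():
    df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [5.0, 5.0, 5.0]})
    out, constant = minmax_scale(df)
    assert list(out["a"]) == [0.0, 0.5, 1.0]
    assert list(out["b"]) == [0.0, 0.0, 0.0]
    assert constant == ["b"]


def test_minmax_scale_idempotent():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
    once, _ = minmax_scale(df)
    twice, _ = minmax_scale(once)
    pd.testing.assert_frame_equal(once, twice)


def test_minmax_ignores_missing():
    df = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
    out, _ = minmax_scale(df)
    assert out["a"].isna().tolist() == [False, True, False]
    assert out["a"].max() == 1.0


def test_pca_two_cluster_structure():
    rng = np.random.default_rng(2)
    n = 8
    base = rng.normal(0, 0.01, size=(2 * n, 5))
    df = pd.DataFrame(base, columns=[f"m{i}" for i in range(5)])
    df.loc[:n - 1, "m2"] += 10.0  # the only separating metabolite
    res = pca(df)
    # loading concentrated on m2
    assert abs(res.loadings.loc["m2", "PC1"]) > 0.99
    a = res.scores.iloc[:n, 0].mean()
    b = res.scores.iloc[n:, 0].mean()
    assert abs(a - b) > 5.0


def test_pca_variance_conservation():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(12, 6)))
    res = pca(df)
    centered = df - df.mean()
    total = centered.to_numpy().var(axis=0, ddof=1).sum()
    assert res.explained_variance.sum() == pytest.approx(total, rel=1e-10)
    assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
    # components ordered by decreasing variance, score columns orthogonal
    assert np.all(np.diff(res.explained_variance) <= 1e-12)
    s = res.scores.to_numpy()
    gram = s.T @ s
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_pca_duplicated_samples_get_identical_scores():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(5, 3)))
    doubled = pd.concat([df, df], ignore_index=True)
    res = pca(doubled)
    np.testing.assert_allclose(
        res.scores.iloc[:5].to_numpy(), res.scores.iloc[5:].to_numpy(), atol=1e-10
    )


def test_pca_needs_two_samples():
    with pytest.raises(ValueError):
        pca(pd.DataFrame({"a": [1.0]}))


def test_welch_example():
    t, df, p = welch_t([1, 2, 3], [2, 3, 4])
    assert t == pytest.approx(-1.2247, abs=1e-4)
    assert df == pytest.approx(4.0)
    assert p == pytest.approx(0.28786, abs=1e-4)


def test_welch_matches_scipy():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a = rng.normal(0, 1, rng.integers(3, 9))
        b = rng.normal(0.5, 2, rng.integers(3, 9))
        t, df, p = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_welch_degenerate_cases():
    assert welch_t([3, 3, 3], [3, 3, 3]) == (0.0, 4.0, 1.0)
    t, _, p = welch_t([1, 1, 1], [5, 5, 5])
    assert p == 0.0 and np.isinf(t)
    with pytest.raises(ValueError):
        welch_t([1.0], [1, 2, 3])


def test_bh_worked_example():
    np.testing.assert_allclose(
        bh_adjust([0.001, 0.013, 0.04, 0.05]), [0.004, 0.026, 0.05, 0.05]
    )


def test_bh_degenerate():
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.5])


def _bh_oracle(p):
    """Literal step-up formula: q(i) = min_{j>=i} p(j)*m/j in sorted order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        q[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_idx, m)), 1.0
        )
    return q


def test_bh_equals_literal_oracle():
    rng = np.random.default_rng(6)
    for _ in range(200):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    p = rng.random(200)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


def test_differential_and_top_k():
    rng = np.random.default_rng(8)
    n = 4
    cols = {f"m{i}": rng.normal(10, 0.2, 2 * n) for i in range(20)}
    for i in range(12):  # 12 clearly shifted metabolites
        cols[f"m{i}"][n:] += 5.0
    df = pd.DataFrame(cols, index=[f"s{i}" for i in range(2 * n)])
    groups = pd.Series(["control"] * n + ["treat"] * n, index=df.index)
    res = differential(df, groups, "control", "treat")
    assert res["p_adj"].ge(res["p"] - 1e-15).all()
    assert res["significant"].sum() >= 12
    top = top_k(res, 10)
    assert len(top) == 10
    few = top_k(res[res.index.isin([f"m{i}" for i in (0, 1, 15)])], 10)
    assert len(few) == 2  # m15 is a null metabolite
    # a named borderline metabolite can be displayed without loosening alpha
    forced = top_k(res[res.index.isin([f"m{i}" for i in (0, 1, 15)])], 10,
                   include=["m15"])
    assert "m15" in forced.index


def test_differential_skips_underpowered_metabolites():
    df = pd.DataFrame({"m": [1.0, np.nan, np.nan, 2.0, 3.0, 4.0]})
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=df.index)
    res = differential(df, groups, "a", "b")
    assert res.loc["m", "skipped"]
    assert np.isnan(res.loc["m", "p_adj"])


def test_top_k_tie_break_deterministic():
    res = pd.DataFrame(
        {
            "p_adj": [0.01, 0.01, 0.01],
            "t": [2.0, -5.0, 2.0],
            "significant": [True, True, True],
        },
        index=pd.Index(["b", "c", "a"], name="metabolite"),
    )
    top = top_k(res, 2)
    assert list(top.index) == ["c", "a"]  # |t| first, then name


def test_rt_logd_perfect_line_and_exclusions():
    rt = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    logd = -0.5 * rt + 1.0
    slope, intercept, r2 = rt_logd_fit(rt, logd)
    assert (slope, intercept, r2) == (pytest.approx(-0.5), pytest.approx(1.0),
                                      pytest.approx(1.0))
    # outliers named for exclusion are removed before fitting
    names = ["a", "b", "c", "d", "outlier"]
    logd2 = logd.copy()
    logd2[-1] += 50
    s2, _, r2b = rt_logd_fit(rt, logd2, names, exclude=["outlier"])
    assert s2 == pytest.approx(-0.5)
    assert r2b == pytest.approx(1.0)


def test_rt_logd_r2_is_pearson_squared():
    rng = np.random.default_rng(9)
    rt = rng.uniform(2, 16, 40)
    logd = -0.3 * rt + rng.normal(0, 1.0, 40)
    _, _, r2 = rt_logd_fit(rt, logd)
    assert r2 == pytest.approx(np.corrcoef(rt, logd)[0, 1] ** 2, abs=1e-10)


def test_welch_null_type_i_error():
    """Empirical alpha at 0.05 for n=4 vs n=4 normal nulls stays near 0.05."""
    rng = np.random.default_rng(10)
    reps = 5000
    a = rng.normal(size=(reps, 4))
    b = rng.normal(size=(reps, 4))
    rejected = sum(welch_t(a[i], b[i])[2] < 0.05 for i in range(reps))
    assert rejected / reps == pytest.approx(0.05, abs=0.01)
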