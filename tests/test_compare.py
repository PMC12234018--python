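"""ANOVA, Levene, planned contrasts, effect sizes, and variance summaries."""

import numpy as np
import pytest
from scipy import stats

from bnseverity.compare import (
    anova,
    exclusion_of_defining_characteristic,
    helmert_contrasts,
    levene_test,
    planned_contrasts,
    variance_summary,
    ComparisonResult,
)


def test_levene_identical_groups_boundary():
    w, p = levene_test([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["a"] * 3 + ["b"] * 3)
    assert w == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_levene_detects_spread_difference():
    vals = [0, 0, 0, 0, -5, 5, -5, 5]
    groups = ["a"] * 4 + ["b"] * 4
    w, p = levene_test(vals, groups)
    # hand ANOVA on absolute deviations from group means: a-deviations all 0,
    # b-deviations all 5 -> infinite separation
    assert w > 1e10 or np.isinf(w)
    assert p < 1e-6


def test_levene_null_p_uniform():
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(300):
        vals = rng.standard_normal(40)
        groups = np.repeat(["a", "b"], 20)
        ps.append(levene_test(vals, rng.permutation(groups))[1])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_levene_degenerate_group_errors():
    with pytest.raises(ValueError, match="fewer than 2"):
        levene_test([1.0, 2.0, 3.0], ["a", "a", "b"])


def test_anova_hand_fixture():
    """Groups (1,2,3) and (2,3,4): SSB=1.5, SSW=4, F = 1.5, eta = 1.5/5.5."""
    res = anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
    # K=2 reduces to the pooled t-test: F = t^2
    assert res.F_or_t**2 == pytest.approx(1.5, abs=1e-10)
    assert res.partial_eta_sq == pytest.approx(1.5 / 5.5, abs=1e-10)


def test_anova_three_groups_matches_scipy():
    rng = np.random.default_rng(4)
    vals = rng.standard_normal(90)
    groups = np.repeat(["a", "b", "c"], 30)
    res = anova(vals, groups)
    f, p = stats.f_oneway(vals[:30], vals[30:60], vals[60:])
    assert res.F_or_t == pytest.approx(f, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)
    assert 0 <= res.partial_eta_sq <= 1


def test_anova_eta_equals_group_regression_r2():
    rng = np.random.default_rng(5)
    vals = np.concatenate([rng.normal(0, 1, 25), rng.normal(0.5, 1, 25), rng.normal(1, 1, 25)])
    groups = np.repeat(["a", "b", "c"], 25)
    res = anova(vals, groups)
    x = np.column_stack([groups == g for g in ("a", "b", "c")]).astype(float)
    beta, *_ = np.linalg.lstsq(x, vals, rcond=None)
    resid = vals - x @ beta
    r2 = 1 - resid.var() / vals.var()
    assert res.partial_eta_sq == pytest.approx(r2, abs=1e-10)


def test_f_equals_t_squared_two_groups():
    rng = np.random.default_rng(6)
    a, b = rng.standard_normal(20), rng.standard_normal(25) + 0.4
    res = anova(np.concatenate([a, b]), ["a"] * 20 + ["b"] * 25)
    t, _ = stats.ttest_ind(a, b)
    assert res.F_or_t == pytest.approx(t, rel=1e-10)


def test_welch_equals_classical_when_balanced_two_groups():
    """At K=2 with exactly equal variances and sizes, the Welch t equals the
    pooled t (Satterthwaite df reduces to n1+n2-2)."""
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = a + 0.5  # identical sample variance, identical n
    vals = np.concatenate([a, b])
    groups = ["a"] * 4 + ["b"] * 4
    classical = anova(vals, groups, welch=False)
    welch = anova(vals, groups, welch=True)
    assert welch.F_or_t == pytest.approx(classical.F_or_t, rel=1e-12)
    assert welch.df[1] == pytest.approx(classical.df[1], rel=1e-12)
    assert welch.p == pytest.approx(classical.p, rel=1e-12)


def test_welch_close_to_classical_balanced_three_groups():
    rng = np.random.default_rng(7)
    vals = rng.standard_normal(600)
    groups = np.repeat(["a", "b", "c"], 200)
    c = anova(vals, groups, welch=False)
    w = anova(vals, groups, welch=True)
    assert w.F_or_t == pytest.approx(c.F_or_t, rel=0.05)


def test_anova_separated_group():
    rng = np.random.default_rng(8)
    vals = np.concatenate([rng.standard_normal(20), rng.standard_normal(20) + 10])
    res = anova(vals, ["a"] * 20 + ["b"] * 20)
    assert res.p < 1e-6


def test_anova_empty_group_errors():
    with pytest.raises(ValueError, match="fewer"):
        anova([1.0, 2.0, 3.0], ["a", "a", "b"])


def test_helmert_coefficients_orthogonal_and_zero_sum():
    order = [1, 2, 3, 4, 5]
    cs = helmert_contrasts(order)
    assert len(cs) == 4
    first = np.array([cs[0][g] for g in order])
    assert np.allclose(first / first[0], [1, -0.25, -0.25, -0.25, -0.25])
    mat = np.array([[c[g] for g in order] for c in cs])
    assert np.allclose(mat.sum(axis=1), 0, atol=1e-12)
    gram = mat @ mat.T
    assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-12)


def test_contrast_estimates_match_pooled_means():
    rng = np.random.default_rng(9)
    vals = np.concatenate(
        [np.zeros(10), np.ones(10), np.full(10, 2.0)]
    ) + rng.normal(0, 1e-9, 30)
    groups = np.repeat([1, 2, 3], 10)
    res = planned_contrasts(vals, groups, [1, 2, 3])
    # contrast 1: group 1 vs mean of higher-group means = (1+2)/2 - 0 = 1.5
    assert res[0].estimate == pytest.approx(1.5, abs=1e-6)
    # contrast 2: group 2 vs group 3 = 2 - 1 = 1.0
    assert res[1].estimate == pytest.approx(1.0, abs=1e-6)
    for c in res:
        assert sum(c.coefficients.values()) == pytest.approx(0, abs=1e-12)


def test_contrast_null_no_effect():
    rng = np.random.default_rng(10)
    vals = rng.standard_normal(60)
    res = planned_contrasts(vals, np.repeat([1, 2], 30), [1, 2])
    a, b = vals[:30], vals[30:]
    t, p = stats.ttest_ind(a, b)
    assert abs(res[0].t) == pytest.approx(abs(t), rel=1e-10)
    assert res[0].p == pytest.approx(p, rel=1e-10)
    assert abs(res[0].cohens_d) < 1.0


def test_contrast_sss_decompose_between_ss_equal_n():
    """Under the equal-n orthogonal convention the K-1 contrast sums of
    squares add up to the between-group sum of squares."""
    rng = np.random.default_rng(11)
    k, n = 4, 30
    vals = np.concatenate([rng.normal(m, 1, n) for m in (0.0, 0.3, 0.8, 1.1)])
    groups = np.repeat([1, 2, 3, 4], n)
    data = {g: vals[groups == g] for g in (1, 2, 3, 4)}
    ss_b = sum(n * (x.mean() - vals.mean()) ** 2 for x in data.values())
    total = 0.0
    for coef in helmert_contrasts([1, 2, 3, 4]):
        c = np.array([coef[g] for g in (1, 2, 3, 4)])
        est = sum(coef[g] * data[g].mean() for g in (1, 2, 3, 4))
        total += est**2 / (c**2 / n).sum()
    assert total == pytest.approx(ss_b, rel=1e-10)


def test_defining_characteristic_exclusions():
    assert exclusion_of_defining_characteristic("dsm5", "comp_freq_weekly")
    assert not exclusion_of_defining_characteristic("semtree", "depression_total")
    assert exclusion_of_defining_characteristic("clinical_overvaluation", "overvaluation")
    with pytest.raises(ValueError, match="unknown scheme"):
        exclusion_of_defining_characteristic("nosuch", "x")


def _cr(scheme, eta):
    return ComparisonResult("c", scheme, 1.0, (1, 10), 0.5, eta, False, {})


def test_variance_summary_and_ratios():
    res = [_cr("a", 0.1), _cr("a", 0.3), _cr("b", 0.05)]
    s = variance_summary(res)
    assert s.per_scheme["a"] == {"min": 0.1, "max": 0.3, "mean": pytest.approx(0.2), "n_characteristics": 2}
    assert s.ratios["a_vs_b"] == pytest.approx(4.0)
    with pytest.raises(ValueError):
        variance_summary([])
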