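"""Statistical battery: formula identities, library cross-checks, null behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from sleepbeat.stats import (DegenerateSampleError, bonferroni,
                             check_summary_consistency, cohens_d_paired,
                             one_way_anova, paired_t, paired_t_batch,
                             partial_eta_squared, t_from_summary,
                             t_interval_from_rounded, two_way_anova)


def test_paired_t_examples():
    res = paired_t(np.zeros(10))
    assert res.statistic == 0.0 and res.p_value == 1.0 and res.effect_size == 0.0
    res = paired_t([1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(3.4641, abs=1e-4)
    assert res.df == (2,)
    with pytest.raises(DegenerateSampleError):
        paired_t([2.0, 2.0, 2.0])
    with pytest.raises(ValueError):
        paired_t([1.0])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_paired_t_matches_scipy(seed):
    d = np.random.default_rng(seed).normal(0.2, 1.0, 15)
    res = paired_t(d)
    t, p = sps.ttest_rel(d, np.zeros_like(d))[:2]
    assert res.statistic == pytest.approx(t, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-12)
    tb, pb = paired_t_batch(np.stack([d, -d]))
    assert tb[0] == pytest.approx(t) and pb[1] == pytest.approx(p)


def test_summary_t_bracketing():
    """A mean of 0.18 +/- 0.20 printed at two decimals is compatible with the
    reported t = 3.461 at n = 15."""
    lo, hi = t_interval_from_rounded(0.18, 0.20, 15)
    assert lo <= 3.461 <= hi
    assert t_from_summary(0.18, 0.20, 15) == pytest.approx(3.4857, abs=1e-3)


@pytest.mark.parametrize(
    "t, n, d",
    [(3.982, 15, 1.028), (-3.108, 15, 0.802), (-5.819, 15, 1.502), (0.0, 15, 0.0)],
)
def test_cohens_d_from_t_identity(t, n, d):
    assert abs(t) / np.sqrt(n) == pytest.approx(d, abs=0.002)


@given(st.integers(0, 1000))
def test_d_equals_t_over_sqrt_n(seed):
    d = np.random.default_rng(seed).normal(0.5, 1.0, 12)
    if d.std(ddof=1) == 0:
        return
    res = paired_t(d)
    assert cohens_d_paired(d) == pytest.approx(abs(res.statistic) / np.sqrt(12), rel=1e-12)


def test_one_way_anova_layout_and_cross_check(rng):
    groups = [rng.normal(0, 1, 15) for _ in range(3)]
    res = one_way_anova(groups)
    assert res.df == (2, 42)
    F, p = sps.f_oneway(*groups)
    assert res.statistic == pytest.approx(F, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-12)
    assert res.effect_size == pytest.approx(
        partial_eta_squared(res.statistic, 2, 42), abs=1e-12
    )
    same = [np.array([1.0, 2.0, 3.0])] * 3
    assert one_way_anova(same).statistic == 0.0
    res4 = one_way_anova([rng.normal(0, 1, 15) for _ in range(4)])
    assert res4.df == (3, 56)


def test_one_way_k2_equals_t_squared(rng):
    g1, g2 = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
    res = one_way_anova([g1, g2])
    t, _ = sps.ttest_ind(g1, g2)[:2]
    assert res.statistic == pytest.approx(t**2, rel=1e-10)


def test_one_way_null_p_uniform(rng):
    ps = []
    for _ in range(1000):
        ps.append(one_way_anova([rng.normal(0, 1, 15) for _ in range(3)]).p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_repeated_measures_variant(rng):
    """Subject-blocked one-way ANOVA agrees with statsmodels AnovaRM."""
    from statsmodels.stats.anova import AnovaRM

    data = rng.normal(0, 1, (10, 3)) + rng.normal(0, 1, (10, 1))
    res = one_way_anova([data[:, j] for j in range(3)], repeated=True)
    long = pd.DataFrame(
        [{"subject": i, "cond": j, "y": data[i, j]} for i in range(10) for j in range(3)]
    )
    rm = AnovaRM(long, "y", "subject", within=["cond"]).fit()
    assert res.statistic == pytest.approx(rm.anova_table["F Value"].iloc[0], rel=1e-8)
    assert res.df == (2, 18)


@pytest.mark.parametrize(
    "F, df1, df2, eta",
    [(3.42, 2, 42, 0.140), (5.70, 3, 56, 0.234), (3.61, 3, 56, 0.162), (0.0, 2, 42, 0.0)],
)
def test_partial_eta_squared_examples(F, df1, df2, eta):
    assert partial_eta_squared(F, df1, df2) == pytest.approx(eta, abs=0.001)
    with pytest.raises(ValueError):
        partial_eta_squared(-1.0, 2, 42)


def test_two_way_anova_layout_and_cross_check(rng):
    """19 x 2 x 15 design yields effect dfs (18, 1, 18); F values agree with
    a statsmodels OLS factorial fit."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    x = rng.normal(0, 1, (19, 2, 15)) + rng.normal(0, 1, (19, 1, 1))
    res = two_way_anova(x)
    assert res["channel"].df == (18, 532)
    assert res["stimulation"].df == (1, 532)
    assert res["interaction"].df == (18, 532)

    small = rng.normal(0, 1, (4, 2, 3))
    mine = two_way_anova(small)
    rows = [
        {"A": f"a{i}", "B": f"b{j}", "y": small[i, j, k]}
        for i in range(4) for j in range(2) for k in range(3)
    ]
    table = sm.stats.anova_lm(ols("y ~ C(A)*C(B)", pd.DataFrame(rows)).fit(), typ=2)
    assert mine["channel"].statistic == pytest.approx(table.loc["C(A)", "F"], rel=1e-9)
    assert mine["stimulation"].statistic == pytest.approx(table.loc["C(B)", "F"], rel=1e-9)
    assert mine["interaction"].statistic == pytest.approx(
        table.loc["C(A):C(B)", "F"], rel=1e-9
    )
    with pytest.raises(ValueError):
        two_way_anova(rng.normal(0, 1, (4, 2, 1)))


def test_two_way_channel_effect_dominates(rng):
    """With only a channel effect injected, the channel F exceeds the
    stimulation F in the overwhelming majority of replicates."""
    wins = 0
    for _ in range(50):
        x = rng.normal(0, 1, (19, 2, 15)) + 2.0 * rng.normal(0, 1, (19, 1, 1))
        res = two_way_anova(x)
        wins += res["channel"].statistic > res["stimulation"].statistic
    assert wins >= 45


def test_bonferroni():
    assert bonferroni(0.01, 3)[0] == pytest.approx(0.03)
    assert bonferroni(0.5, 6)[0] == 1.0
    out = bonferroni([0.001, 0.02, 0.5], 3)
    assert np.allclose(out, [0.003, 0.06, 1.0])
    with pytest.raises(ValueError):
        bonferroni(0.01, 0)


@given(st.floats(0, 1), st.integers(1, 100))
def test_bonferroni_caps_and_orders(p, m):
    adj = bonferroni(p, m)[0]
    assert p <= adj <= 1.0


def test_consistency_checker_flags_typos():
    table = pd.DataFrame([
        {"condition": "X", "band": "theta", "mean": 0.18, "sd": 0.20, "t": 3.461, "p": 0.003},
        {"condition": "X", "band": "delta", "mean": 0.25, "sd": 0.80, "t": 1.888, "p": 0.254},
    ])
    out = check_summary_consistency(table, n=15)
    assert bool(out.loc[0, "consistent"]) is True
    assert bool(out.loc[1, "consistent"]) is False
    # the typo row's printed p matches the recomputed t, not the printed one
    assert bool(out.loc[1, "t_p_coherent"]) is False
    assert out.loc[1, "t_recomputed"] == pytest.approx(1.21, abs=0.01)
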