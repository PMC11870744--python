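"""Group statistics against exhaustive enumeration and reference implementations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senpatch import stats

# ------------------------------------------------------------------ oracles


def fisher_enum_p(table) -> float:
    """Two-sided Fisher p by direct enumeration with math.comb only."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def mw_enum_p(x, y) -> float:
    """Two-sided Mann-Whitney p by enumeration over group assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    n = len(pooled)

    def u_of(idx):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        ranks = pd.Series(pooled).rank().to_numpy()
        return ranks[mask].sum() - nx * (nx + 1) / 2

    mu = nx * (n - nx) / 2
    d_obs = abs(u_of(range(nx)) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), nx):
        total += 1
        if abs(u_of(comb) - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


# ------------------------------------------------------------------- Fisher


def test_fisher_diagonal_table_matches_closed_form():
    # p([[10,0],[0,10]]) = 2 / C(20,10): only the two extreme tables qualify
    res = stats.fisher_exact_2x2([[10, 0], [0, 10]])
    assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
    assert res.haldane_corrected


def test_fisher_symmetric_table_is_null():
    res = stats.fisher_exact_2x2([[5, 5], [5, 5]])
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration_on_small_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        t = rng.integers(1, 11, size=(2, 2))
        res = stats.fisher_exact_2x2(t)
        assert res.p_value == pytest.approx(fisher_enum_p(t), rel=1e-9), t


def test_fisher_matches_scipy_probability_mass_rule():
    from scipy.stats import fisher_exact

    rng = np.random.default_rng(1)
    for _ in range(200):
        t = rng.integers(0, 15, size=(2, 2))
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            continue
        assert stats.fisher_exact_2x2(t).p_value == pytest.approx(
            fisher_exact(t)[1], rel=1e-8), t


def test_fisher_rejects_empty_margin():
    with pytest.raises(ValueError):
        stats.fisher_exact_2x2([[0, 0], [3, 4]])


# ------------------------------------------------------------- Mann-Whitney


def test_mw_constant_data_gives_p_one():
    res = stats.mann_whitney([3.0] * 5, [3.0] * 20)
    assert res.p_value == 1.0


@pytest.mark.parametrize("seed", range(10))
def test_mw_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 6, size=4).astype(float)  # small support forces ties
    y = rng.integers(0, 6, size=4).astype(float)
    res = stats.mann_whitney(x, y)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(mw_enum_p(x, y), rel=1e-12)


def test_mw_exact_matches_scipy_without_ties():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(3)
    for _ in range(20):
        x, y = rng.normal(size=5), rng.normal(size=6)
        res = stats.mann_whitney(x, y)
        ref = mannwhitneyu(x, y, method="exact")
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def test_mw_power_is_monotone_in_shift():
    rng = np.random.default_rng(5)
    rejections = []
    for shift in (0.0, 1.0, 2.0):
        rej = 0
        for _ in range(200):
            x = rng.normal(size=15)
            y = rng.normal(loc=shift, size=15)
            rej += stats.mann_whitney(x, y).p_value < 0.05
        rejections.append(rej)
    assert rejections[0] < rejections[1] < rejections[2]


# ------------------------------------------------------------ Kruskal-Dunn


def test_kruskal_identical_groups_h_near_zero():
    g = [[2.0, 2.0, 2.0], [2.0, 2.0, 2.0], [2.0, 2.0, 2.0]]
    res = stats.kruskal_dunn(g)
    assert res.h_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_kruskal_h_matches_scipy_with_ties():
    from scipy.stats import kruskal

    rng = np.random.default_rng(2)
    for _ in range(50):
        groups = [rng.integers(0, 8, size=rng.integers(3, 8)).astype(float)
                  for _ in range(3)]
        res = stats.kruskal_dunn(groups)
        ref = kruskal(*groups)
        assert res.h_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def test_kruskal_h_matches_rank_definition_by_enumeration():
    """H computed from first principles over every assignment of 6 ranks."""
    values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    n = 6
    for comb in itertools.combinations(range(n), 2):
        rest = [i for i in range(n) if i not in comb]
        groups = [values[list(comb)], values[rest[:2]], values[rest[2:]]]
        res = stats.kruskal_dunn(groups)
        ranks = pd.Series(np.concatenate(groups)).rank().to_numpy()
        sizes = [2, 2, 2]
        bounds = np.cumsum([0] + sizes)
        h = 12 / (n * (n + 1)) * sum(
            ranks[bounds[i]:bounds[i + 1]].sum() ** 2 / sizes[i] for i in range(3)
        ) - 3 * (n + 1)
        assert res.h_statistic == pytest.approx(h, rel=1e-12)


def test_dunn_adjusted_never_below_raw():
    rng = np.random.default_rng(4)
    for adjust in ("bonferroni", "holm", "sidak"):
        groups = [rng.normal(loc=m, size=6) for m in (0, 0.5, 2.0, 0.1)]
        res = stats.kruskal_dunn(groups, adjust=adjust)
        assert (res.pairwise["p_adjusted"] >= res.pairwise["p_raw"] - 1e-15).all()


def test_dunn_merging_identical_groups_does_not_gain_significance():
    rng = np.random.default_rng(6)
    base = rng.normal(size=8)
    shifted = rng.normal(loc=3.0, size=8)
    # three groups where two are identical copies vs the merged two-group case
    res3 = stats.kruskal_dunn([base, base.copy(), shifted])
    res2 = stats.kruskal_dunn([np.concatenate([base, base]), shifted])
    pair3 = res3.pairwise.set_index(["group_a", "group_b"])
    p_split = pair3.loc[("group0", "group2"), "p_adjusted"]
    p_merged = res2.pairwise["p_adjusted"].iloc[0]
    assert p_merged <= p_split + 1e-12


# ----------------------------------------------------------------- logrank


def test_logrank_identical_arms_chi_square_zero():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.ones(4, bool)
    res = stats.logrank(t, e, t, e)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)


def test_logrank_fully_separated_arms_from_closed_form():
    # all arm-A events precede every arm-B event; O-E terms are hand-computable
    ta = np.arange(1.0, 11.0)
    tb = np.arange(20.0, 30.0)
    e = np.ones(10, bool)
    res = stats.logrank(ta, e, tb, e)
    assert res.p_value < 0.01
    assert res.observed[0] == 10.0


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(8)
    for _ in range(20):
        ta = rng.exponential(10, 15)
        tb = rng.exponential(18, 12)
        ea = ta < 25
        eb = tb < 25
        res = stats.logrank(np.minimum(ta, 25), ea, np.minimum(tb, 25), eb)
        ref = logrank_test(np.minimum(ta, 25), np.minimum(tb, 25), ea, eb)
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_censoring_only_arm_is_handled():
    res = stats.logrank([5.0, 5.0], [False, False], [1.0, 2.0], [True, True])
    assert np.isfinite(res.chi_square)


def test_kaplan_meier_matches_product_limit_by_hand():
    # times 1 (event), 2 (censored), 3 (event): S(1) = 2/3 with 3 at risk,
    # then the last subject dies alone at t = 3, so S(3) = 2/3 * 0 = 0
    km = stats.kaplan_meier([1.0, 2.0, 3.0], [True, False, True])
    surv = dict(zip(km["time"], km["survival"]))
    assert surv[1.0] == pytest.approx(2 / 3)
    assert surv[3.0] == pytest.approx(0.0)


# -------------------------------------------------------- fraction report


def test_marker_fraction_percentages_and_exclusion():
    cells = pd.DataFrame({
        "sample": ["a"] * 4 + ["b"] * 4 + ["c"] * 2,
        "marker_pos": [True, True, False, False, True, False, False, False,
                       True, False],
        "neun_pos": [True] * 8 + [False] * 2,
    })
    rep = stats.marker_fraction_report(cells)
    by = rep.set_index("sample")
    assert by.loc["a", "percent"] == pytest.approx(50.0)
    assert by.loc["b", "percent"] == pytest.approx(25.0)
    assert bool(by.loc["c", "excluded"])
    assert rep.attrs["mean"] == pytest.approx(37.5)


def test_marker_fraction_all_positive_is_100_percent():
    cells = pd.DataFrame({"sample": ["s"] * 5, "marker_pos": [True] * 5,
                          "neun_pos": [True] * 5})
    rep = stats.marker_fraction_report(cells)
    assert rep.set_index("sample").loc["s", "percent"] == pytest.approx(100.0)


# ------------------------------------------------- hypothesis property tests


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 12), min_size=4, max_size=4))
def test_fisher_probability_mass_rule_is_enumeration(cells):
    t = [[cells[0], cells[1]], [cells[2], cells[3]]]
    assert stats.fisher_exact_2x2(t).p_value == pytest.approx(
        fisher_enum_p(t), rel=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=5),
       st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=5))
def test_mw_p_value_is_a_probability_and_symmetric(x, y):
    res_xy = stats.mann_whitney(x, y)
    res_yx = stats.mann_whitney(y, x)
    assert 0.0 <= res_xy.p_value <= 1.0
    assert res_xy.p_value == pytest.approx(res_yx.p_value, rel=1e-12)
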