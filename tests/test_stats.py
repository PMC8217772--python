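import itertools

import numpy as np
import pytest
from scipy import stats as sps

from nudpa.phantoms import simulate_quant_table
from nudpa.stats import (
    _holm,
    friedman_statistic,
    friedman_test,
    kruskal_wallis,
    normality_diagnostics,
    repeated_measures_anova,
    run_region_stats,
    select_test,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Test selection
# ---------------------------------------------------------------------------


def test_select_test_families():
    plan = select_test(6, paired=True, n_groups=2)
    assert plan.family == "nonparametric"
    assert plan.omnibus_test == "wilcoxon_signed_rank"
    assert plan.posthoc_test is None

    plan = select_test(6, paired=True, n_groups=3)
    assert plan.omnibus_test == "friedman"
    assert plan.posthoc_test == "wilcoxon_signed_rank"

    plan = select_test(6, paired=False, n_groups=2)
    assert plan.omnibus_test == "wilcoxon_rank_sum"
    plan = select_test(6, paired=False, n_groups=4)
    assert plan.omnibus_test == "kruskal_wallis"
    assert plan.posthoc_test == "wilcoxon_rank_sum"

    plan = select_test(30, paired=True, n_groups=2)
    assert plan.family == "parametric" and plan.omnibus_test == "paired_t"
    assert select_test(30, True, 3).omnibus_test == "repeated_measures_anova"
    assert select_test(30, False, 2).omnibus_test == "two_sample_t"
    assert select_test(30, False, 3).omnibus_test == "one_way_anova"

    with pytest.raises(ValueError):
        select_test(5, True, 1)
    with pytest.raises(ValueError):
        select_test(1, True, 2)


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------


def test_friedman_statistic_strict_ordering():
    # 6 subjects x 3 conditions, same strict ordering everywhere -> chi2 = 12
    values = np.tile([1.0, 2.0, 3.0], (6, 1))
    assert friedman_statistic(values) == pytest.approx(12.0, abs=1e-12)


def test_friedman_statistic_matches_scipy_no_ties():
    rng = np.random.default_rng(0)
    for _ in range(10):
        values = rng.normal(size=(7, 4))
        ours = friedman_statistic(values)
        ref = sps.friedmanchisquare(*(values[:, j] for j in range(4))).statistic
        assert ours == pytest.approx(ref, rel=1e-10)


def _friedman_brute_force_p(values):
    """Enumerate all k!^n within-subject permutations directly.

    Only the column rank sums enter the statistic, so each subject
    contributes one of k! permuted rank rows; the full product is enumerated
    as an outer sum of those rows.
    """
    values = np.asarray(values, float)
    n, k = values.shape
    observed = friedman_statistic(values)
    ranks = np.apply_along_axis(lambda r: sps.rankdata(r, method="average"),
                                1, values)
    denom = float(((ranks - (k + 1) / 2.0) ** 2).sum())
    scale = (k - 1) / denom
    perms = np.array(list(itertools.permutations(range(k))))
    col_sums = np.zeros((1, k))
    for i in range(n):
        rows = ranks[i][perms]  # (k!, k) permuted rank rows for subject i
        col_sums = (col_sums[:, None, :] + rows[None, :, :]).reshape(-1, k)
    center = n * (k + 1) / 2.0
    stats_all = scale * ((col_sums - center) ** 2).sum(axis=1)
    return float((stats_all >= observed - 1e-9).mean())


@pytest.mark.parametrize("n,k,seed", [(4, 3, 1), (5, 3, 2), (4, 4, 3)])
def test_friedman_exact_agrees_with_brute_force(n, k, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n, k))
    _, p = friedman_test(values)
    assert p == pytest.approx(_friedman_brute_force_p(values), abs=1e-12)


def test_friedman_exact_with_ties():
    values = np.array([[1.0, 1.0, 2.0], [3.0, 1.0, 2.0],
                       [2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
    _, p = friedman_test(values)
    assert p == pytest.approx(_friedman_brute_force_p(values), abs=1e-12)


def test_friedman_large_n_uses_chi2():
    rng = np.random.default_rng(4)
    values = rng.normal(size=(12, 3))
    stat, p = friedman_test(values)
    assert p == pytest.approx(float(sps.chi2.sf(stat, 2)), rel=1e-12)


def test_friedman_input_validation():
    with pytest.raises(ValueError):
        friedman_test(np.ones((1, 3)))
    with pytest.raises(ValueError):
        friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def test_signed_rank_exact_small_example():
    # n=5, all differences positive -> W+ = 15, two-sided p = 2/32
    x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
    w, p = wilcoxon_signed_rank(x, y)
    assert w == 15.0
    assert p == pytest.approx(2 / 32, abs=1e-12)


def test_signed_rank_matches_scipy_exact():
    rng = np.random.default_rng(7)
    for _ in range(20):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        w, p = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, mode="exact")
        # scipy reports min(W+, W-); p-values must agree
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_signed_rank_zero_differences():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert wilcoxon_signed_rank(x, x) == (0.0, 1.0)
    # one informative pair remains after dropping zeros
    y = x.copy()
    y[0] += 1.0
    _, p = wilcoxon_signed_rank(x, y)
    assert 0 < p <= 1


def test_signed_rank_normal_approximation_large_n():
    rng = np.random.default_rng(8)
    x = rng.normal(size=40)
    y = x + rng.normal(0.5, 1.0, size=40)
    _, p = wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(x, y, correction=True, mode="approx")
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_signed_rank_validation():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1.0], [2.0])
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def test_rank_sum_exact_small_example():
    # complete separation, n=m=4 -> two-sided p = 2/70
    x = np.array([10.0, 11.0, 12.0, 13.0])
    y = np.array([1.0, 2.0, 3.0, 4.0])
    u, p = wilcoxon_rank_sum(x, y)
    assert u == 16.0
    assert p == pytest.approx(2 / 70, abs=1e-12)


def test_rank_sum_matches_scipy_exact():
    rng = np.random.default_rng(9)
    for _ in range(20):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        u, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_rank_sum_normal_approx_with_ties():
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 8.0, 9.0, 9.0, 10.0, 11.0])
    y = np.array([2.0, 2.0, 4.0, 5.0, 5.0, 7.0, 9.0, 9.0, 12.0, 13.0])
    _, p = wilcoxon_rank_sum(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_rank_sum_validation():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Other tests and diagnostics
# ---------------------------------------------------------------------------


def test_kruskal_wallis_matches_scipy():
    rng = np.random.default_rng(10)
    groups = [rng.normal(size=6) for _ in range(3)]
    stat, p = kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert stat == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_repeated_measures_anova_matches_reference():
    rng = np.random.default_rng(11)
    mat = rng.normal(size=(10, 3)) + np.array([0.0, 0.5, 1.0])
    f, p = repeated_measures_anova(mat)
    # reference via statsmodels AnovaRM
    import pandas as pd
    from statsmodels.stats.anova import AnovaRM

    long = pd.DataFrame(
        [
            {"subject": i, "cond": j, "value": mat[i, j]}
            for i in range(10)
            for j in range(3)
        ]
    )
    res = AnovaRM(long, "value", "subject", within=["cond"]).fit()
    assert f == pytest.approx(float(res.anova_table["F Value"].iloc[0]), rel=1e-9)
    assert p == pytest.approx(float(res.anova_table["Pr > F"].iloc[0]), rel=1e-9)


def test_normality_diagnostics():
    rng = np.random.default_rng(12)
    vals = rng.normal(size=25)
    sh, ad, qq = normality_diagnostics(vals)
    assert 0 <= sh <= 1 and 0 <= ad <= 1
    assert qq.shape == (25, 2)
    assert np.all(np.diff(qq[:, 1]) >= 0)
    with pytest.raises(ValueError):
        normality_diagnostics([1.0, 2.0])
    with pytest.raises(ValueError):
        normality_diagnostics([3.0, 3.0, 3.0])


def test_holm_correction():
    p = np.array([0.01, 0.04, 0.03, 0.005])
    adj = _holm(p)
    # classic Holm: sorted p * (m - rank), running max, capped at 1
    assert adj[3] == pytest.approx(0.02)
    assert adj[0] == pytest.approx(0.03)
    assert np.all(adj <= 1.0) and np.all(adj >= p)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def test_run_region_stats_paired_three_states(tmp_path):
    table = simulate_quant_table(
        6, ["control", "mild", "severe"],
        {"cortex": 1.0, "thalamus": 0.8},
        effects={"severe": {"cortex": 1.6}},
        seed=3,
    )
    res = run_region_stats(table, "state", paired=True, parameters=("UR",),
                           plot_dir=tmp_path)
    assert set(res["region"]) == {"cortex", "thalamus"}
    assert (res["test"] == "friedman").all()
    posthoc_cols = [c for c in res.columns if c.startswith("posthoc_")]
    assert len(posthoc_cols) == 3
    # plots written per region
    assert len(list(tmp_path.glob("*_boxplot.png"))) == 2
    assert len(list(tmp_path.glob("*_qq.svg"))) == 2


def test_run_region_stats_detects_effect():
    table = simulate_quant_table(
        8, ["control", "lesion"], {"cortex": 1.0},
        effects={"lesion": {"cortex": 2.0}}, cv=0.05, seed=4,
    )
    res = run_region_stats(table, "state", paired=True)
    assert res["test"].item() == "wilcoxon_signed_rank"
    assert res["p_value"].item() < 0.05


def test_run_region_stats_skips_incomplete_pairs():
    table = simulate_quant_table(4, ["control", "lesion"], {"cortex": 1.0},
                                 seed=5)
    table = table[~((table["animal_id"] == "S1") &
                    (table["state"] == "lesion"))]
    with pytest.warns(UserWarning, match="missing animals"):
        res = run_region_stats(table, "state", paired=True)
    assert res.empty


def test_run_region_stats_unpaired():
    table = simulate_quant_table(6, ["control", "lesion"], {"cortex": 1.0},
                                 seed=6)
    res = run_region_stats(table, "state", paired=False)
    assert res["test"].item() == "wilcoxon_rank_sum"


def test_run_region_stats_holm():
    table = simulate_quant_table(
        6, ["control", "lesion"],
        {f"r{i}": 1.0 for i in range(4)}, seed=7,
    )
    res = run_region_stats(table, "state", paired=True, holm_correction=True)
    assert "p_value_holm" in res.columns
    assert (res["p_value_holm"] >= res["p_value"] - 1e-12).all()


def test_type_one_error_calibration():
    """Null rejection rate of the paired pipeline stays near alpha."""
    alpha = 0.05
    rejections = 0
    n_cohorts = 200
    for c in range(n_cohorts):
        table = simulate_quant_table(8, ["control", "lesion"],
                                     {"cortex": 1.0}, seed=10_000 + c)
        res = run_region_stats(table, "state", paired=True)
        if res["p_value"].item() < alpha:
            rejections += 1
    rate = rejections / n_cohorts
    assert 0.01 <= rate <= 0.12
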