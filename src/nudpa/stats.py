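"""Automated group statistics per atlas region and frame interval.

The test family is chosen from the per-group sample size: nonparametric for
n < 30 and parametric for n >= 30.  For paired nonparametric designs the
omnibus test is the Wilcoxon signed-rank test (two groups) or the Friedman
test (more than two) with Wilcoxon signed-rank post hocs; unpaired designs
use the rank-sum and Kruskal-Wallis tests.  The rank tests here use exact
small-sample distributions (sign enumeration, label-permutation counting,
within-subject permutation) and fall back to the standard large-sample
approximations; this matters because typical preclinical group sizes are far
below the asymptotic regime.

Normality diagnostics (Shapiro-Wilk, Anderson-Darling, QQ points) and
per-region boxplots with individual animal values accompany every result so
the choice of test family can be verified.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad

PARAMETRIC_N = 30  # per-group sample size at which parametric tests engage


@dataclass
class StatPlan:
    n_per_group: int
    paired: bool
    n_groups: int
    family: str  # parametric | nonparametric
    omnibus_test: str
    posthoc_test: str | None


@dataclass
class StatResult:
    region: str
    interval: str
    parameter: str
    test: str
    statistic: float
    p_value: float
    posthoc: list[tuple[str, float]] = field(default_factory=list)
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Test selection
# ---------------------------------------------------------------------------


def select_test(n_per_group: int, paired: bool, n_groups: int) -> StatPlan:
    """Choose the test family and omnibus/post-hoc tests for a design."""
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if n_per_group < 2:
        raise ValueError("need at least two observations per group")
    family = "parametric" if n_per_group >= PARAMETRIC_N else "nonparametric"
    if family == "nonparametric":
        if paired:
            omnibus = "wilcoxon_signed_rank" if n_groups == 2 else "friedman"
            posthoc = "wilcoxon_signed_rank" if n_groups > 2 else None
        else:
            omnibus = "wilcoxon_rank_sum" if n_groups == 2 else "kruskal_wallis"
            posthoc = "wilcoxon_rank_sum" if n_groups > 2 else None
    else:
        if paired:
            omnibus = "paired_t" if n_groups == 2 else "repeated_measures_anova"
            posthoc = "paired_t" if n_groups > 2 else None
        else:
            omnibus = "two_sample_t" if n_groups == 2 else "one_way_anova"
            posthoc = "two_sample_t" if n_groups > 2 else None
    return StatPlan(n_per_group, paired, n_groups, family, omnibus, posthoc)


# ---------------------------------------------------------------------------
# Rank tests with exact small-sample distributions
# ---------------------------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def friedman_statistic(values: np.ndarray) -> float:
    """Friedman chi-square statistic with mid-rank ties and tie correction."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = np.apply_along_axis(_midranks, 1, values)
    col_sums = ranks.sum(axis=0)
    ss = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    # tie correction: scale by the rank variance actually present
    denom = float(((ranks - (k + 1) / 2.0) ** 2).sum())
    if denom == 0:
        return 0.0
    return (k - 1) * n * ss / denom / n


def friedman_test(
    values: np.ndarray, *, exact_max_subjects: int = 8
) -> tuple[float, float]:
    """Friedman test on a subjects x groups matrix.

    The p-value is exact (full within-subject permutation distribution,
    computed by dynamic programming over rank-sum vectors) for up to
    ``exact_max_subjects`` subjects, chi-square approximated otherwise.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a subjects x groups matrix with >=2 of each")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells are not allowed")
    n, k = values.shape
    stat = friedman_statistic(values)
    if n <= exact_max_subjects:
        p = _friedman_exact_p(values, stat)
    else:
        p = float(sps.chi2.sf(stat, k - 1))
    return stat, min(max(p, 0.0), 1.0)


def _friedman_exact_p(values: np.ndarray, observed: float) -> float:
    """Exact permutation p by convolving per-subject rank-sum distributions."""
    n, k = values.shape
    ranks = np.apply_along_axis(_midranks, 1, values)
    denom = float(((ranks - (k + 1) / 2.0) ** 2).sum())
    if denom == 0:
        return 1.0
    scale = (k - 1) / denom  # statistic = scale * sum((colsum - n(k+1)/2)^2)

    # distribution over rank-sum vectors, advanced one subject at a time
    dist: dict[tuple, float] = {tuple([0.0] * k): 1.0}
    for i in range(n):
        perms = set(itertools.permutations(np.round(ranks[i], 9)))
        new: dict[tuple, float] = {}
        w = 1.0 / len(perms)
        for state, prob in dist.items():
            for perm in perms:
                key = tuple(round(s + r, 9) for s, r in zip(state, perm))
                new[key] = new.get(key, 0.0) + prob * w
        dist = new
    center = n * (k + 1) / 2.0
    p = 0.0
    for state, prob in dist.items():
        stat = scale * sum((s - center) ** 2 for s in state)
        if stat >= observed - 1e-9:
            p += prob
    return p


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped; ties get mid-ranks.  The null distribution
    of W+ is enumerated exactly over all sign assignments for n <= 15 and
    normally approximated (with continuity correction) beyond.  Returns
    (W+, p).  All-zero differences are degenerate: p = 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    r = _midranks(np.abs(d))
    w_plus = float(r[d > 0].sum())
    total = n * (n + 1) / 2.0
    if n <= 15:
        # enumerate all 2^n sign assignments of the mid-ranks
        stats_all = np.zeros(1)
        for ri in r:
            stats_all = np.concatenate([stats_all, stats_all + ri])
        lo = float((stats_all <= w_plus + 1e-9).mean())
        hi = float((stats_all >= w_plus - 1e-9).mean())
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        mean = total / 2.0
        # variance with tie correction over the mid-ranks
        var = float((r**2).sum()) / 4.0
        z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
        p = float(2 * sps.norm.sf(max(z, 0.0)))
    return w_plus, min(p, 1.0)


def _mann_whitney_exact_sf(n: int, m: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic (no ties) by recursion."""
    # count[u] = number of arrangements with U = u
    counts = np.zeros(n * m + 1)
    counts[0] = 1.0
    # classic generating function: prod_{i=1..n} (1 - q^{m+i}) / (1 - q^i)
    # computed by iterative polynomial updates
    for i in range(1, n + 1):
        new = np.zeros_like(counts)
        for u in range(counts.size):
            new[u] = counts[u] + (new[u - i] if u >= i else 0.0)
            if u >= m + i:
                new[u] -= counts[u - (m + i)]
        counts = new
    return counts / comb(n + m, n)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise.  Returns (U of x, p).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    rx = float(ranks[:n].sum())
    u = rx - n * (n + 1) / 2.0
    has_ties = np.unique(combined).size < combined.size
    if n + m <= 20 and not has_ties:
        pmf = _mann_whitney_exact_sf(n, m)
        ui = int(round(u))
        lo = float(pmf[: ui + 1].sum())
        hi = float(pmf[ui:].sum())
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        mean = n * m / 2.0
        tie_term = 0.0
        for _, cnt in zip(*np.unique(combined, return_counts=True)):
            if cnt > 1:
                tie_term += cnt**3 - cnt
        var = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
        if var == 0:
            return u, 1.0
        z = (abs(u - mean) - 0.5) / np.sqrt(var)
        p = float(2 * sps.norm.sf(max(z, 0.0)))
    return u, min(p, 1.0)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H test across >=3 unpaired groups."""
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Normality diagnostics
# ---------------------------------------------------------------------------


def normality_diagnostics(values) -> tuple[float, float, np.ndarray]:
    """Shapiro-Wilk and Anderson-Darling p-values plus QQ-plot points."""
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("constant input has no distribution to test")
    shapiro_p = float(sps.shapiro(values).pvalue)
    _, anderson_p = normal_ad(values)
    srt = np.sort(values)
    qq_theoretical = sps.norm.ppf((np.arange(1, values.size + 1) - 0.5) / values.size)
    qq = np.column_stack([qq_theoretical, srt])
    return shapiro_p, float(anderson_p), qq


# ---------------------------------------------------------------------------
# Orchestration over a quantification table
# ---------------------------------------------------------------------------

def repeated_measures_anova(mat: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on a subjects x groups matrix."""
    mat = np.asarray(mat, float)
    n, k = mat.shape
    grand = mat.mean()
    ss_treat = n * float(((mat.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((mat.mean(axis=1) - grand) ** 2).sum())
    ss_err = float(((mat - grand) ** 2).sum()) - ss_treat - ss_subj
    df_t, df_e = k - 1, (k - 1) * (n - 1)
    if ss_err <= 0:
        return float("inf") if ss_treat > 0 else 0.0, 0.0 if ss_treat > 0 else 1.0
    f = (ss_treat / df_t) / (ss_err / df_e)
    return f, float(sps.f.sf(f, df_t, df_e))


_OMNIBUS = {
    "friedman": lambda mat: friedman_test(mat),
    "repeated_measures_anova": repeated_measures_anova,
    "wilcoxon_signed_rank": lambda mat: wilcoxon_signed_rank(mat[:, 0], mat[:, 1]),
    "wilcoxon_rank_sum": lambda mat: wilcoxon_rank_sum(mat[:, 0], mat[:, 1]),
    "kruskal_wallis": lambda mat: kruskal_wallis([mat[:, j] for j in range(mat.shape[1])]),
    "paired_t": lambda mat: tuple(
        float(v) for v in sps.ttest_rel(mat[:, 0], mat[:, 1])[:2]
    ),
    "two_sample_t": lambda mat: tuple(
        float(v) for v in sps.ttest_ind(mat[:, 0], mat[:, 1])[:2]
    ),
    "one_way_anova": lambda mat: tuple(
        float(v)
        for v in sps.f_oneway(*[mat[:, j] for j in range(mat.shape[1])])[:2]
    ),
}


def _posthoc_pair(test: str, a: np.ndarray, b: np.ndarray) -> float:
    if test == "wilcoxon_signed_rank":
        return wilcoxon_signed_rank(a, b)[1]
    if test == "wilcoxon_rank_sum":
        return wilcoxon_rank_sum(a, b)[1]
    if test == "paired_t":
        return float(sps.ttest_rel(a, b).pvalue)
    if test == "two_sample_t":
        return float(sps.ttest_ind(a, b).pvalue)
    raise ValueError(f"unknown post-hoc test: {test}")


def run_region_stats(
    quant_table: pd.DataFrame,
    group_column: str = "state",
    *,
    paired: bool = True,
    parameters: tuple[str, ...] = ("UR",),
    plot_dir: str | Path | None = None,
    holm_correction: bool = False,
) -> pd.DataFrame:
    """Run omnibus + post-hoc tests per region x interval x parameter.

    ``quant_table`` is the tidy quantification output.  In a paired design,
    regions with animals missing from any group are skipped with a warning.
    When ``plot_dir`` is given, a boxplot with individual animal values and a
    per-group QQ plot are written per combination.  Returns one tidy result
    table; p-values are uncorrected across regions unless ``holm_correction``.
    """
    results: list[dict] = []
    plot_dir = Path(plot_dir) if plot_dir is not None else None
    if plot_dir is not None:
        plot_dir.mkdir(parents=True, exist_ok=True)

    for (region, interval, param), sub in quant_table[
        quant_table["parameter"].isin(parameters)
    ].groupby(["region", "interval", "parameter"], sort=True):
        groups = sorted(sub[group_column].unique())
        if len(groups) < 2:
            continue
        if paired:
            pivot = sub.pivot_table(
                index="animal_id", columns=group_column, values="value"
            )[groups]
            if pivot.isna().any().any():
                warnings.warn(
                    f"region {region!r} {interval}: missing animals in paired "
                    "design; skipped",
                    stacklevel=2,
                )
                continue
            mat = pivot.to_numpy()
            n_per_group = mat.shape[0]
            samples = {g: mat[:, j] for j, g in enumerate(groups)}
        else:
            samples = {
                g: sub.loc[sub[group_column] == g, "value"].to_numpy()
                for g in groups
            }
            n_per_group = min(len(v) for v in samples.values())
            mat = None
        plan = select_test(n_per_group, paired, len(groups))

        if mat is None:
            if plan.omnibus_test == "wilcoxon_rank_sum":
                stat, p = wilcoxon_rank_sum(samples[groups[0]], samples[groups[1]])
            elif plan.omnibus_test == "two_sample_t":
                stat, p = (float(v) for v in
                           sps.ttest_ind(samples[groups[0]], samples[groups[1]])[:2])
            elif plan.omnibus_test == "kruskal_wallis":
                stat, p = kruskal_wallis(list(samples.values()))
            else:
                stat, p = (float(v) for v in sps.f_oneway(*samples.values())[:2])
        else:
            stat, p = _OMNIBUS[plan.omnibus_test](mat)

        posthoc: list[tuple[str, float]] = []
        if plan.posthoc_test is not None:
            for ga, gb in itertools.combinations(groups, 2):
                posthoc.append(
                    (f"{ga}-{gb}", _posthoc_pair(plan.posthoc_test, samples[ga], samples[gb]))
                )
        normality = {}
        for g, vals in samples.items():
            try:
                sh, ad, _ = normality_diagnostics(vals)
                normality[g] = (sh, ad)
            except ValueError:
                normality[g] = (float("nan"), float("nan"))
        if plot_dir is not None:
            _emit_plots(plot_dir, region, interval, param, samples)
        row = {
            "region": region,
            "interval": interval,
            "parameter": param,
            "family": plan.family,
            "test": plan.omnibus_test,
            "statistic": stat,
            "p_value": p,
        }
        for pair, pv in posthoc:
            row[f"posthoc_{pair}"] = pv
        for g, (sh, ad) in normality.items():
            row[f"shapiro_p_{g}"] = sh
            row[f"anderson_p_{g}"] = ad
        results.append(row)
    table = pd.DataFrame(results)
    if holm_correction and not table.empty:
        for (interval, param), idx in table.groupby(["interval", "parameter"]).groups.items():
            pvals = table.loc[idx, "p_value"].to_numpy()
            table.loc[idx, "p_value_holm"] = _holm(pvals)
    return table


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in str(text))


def _emit_plots(plot_dir: Path, region, interval, param, samples: dict) -> None:
    base = f"{_slug(region)}_{_slug(interval)}_{_slug(param)}"
    groups = list(samples)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot([samples[g] for g in groups], tick_labels=groups)
    rng = np.random.default_rng(0)
    for j, g in enumerate(groups, start=1):
        vals = samples[g]
        ax.plot(j + rng.uniform(-0.08, 0.08, len(vals)), vals, "o", ms=4, alpha=0.7)
    ax.set_title(f"{region} {interval}")
    ax.set_ylabel(param)
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(plot_dir / f"{base}_boxplot.{ext}")
    plt.close(fig)

    fig, axes = plt.subplots(1, len(groups), figsize=(3 * len(groups), 3),
                             squeeze=False)
    for ax, g in zip(axes[0], groups):
        vals = np.asarray(samples[g], float)
        if vals.size >= 3 and np.ptp(vals) > 0:
            _, _, qq = normality_diagnostics(vals)
            ax.plot(qq[:, 0], qq[:, 1], "o", ms=4)
            lim = [qq[:, 0].min(), qq[:, 0].max()]
            mu, sd = vals.mean(), vals.std(ddof=1)
            ax.plot(lim, [mu + sd * v for v in lim], "-", lw=1)
        ax.set_title(g)
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(plot_dir / f"{base}_qq.{ext}")
    plt.close(fig)
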