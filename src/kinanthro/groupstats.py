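"""Positional comparison battery: assumption-driven test selection, omnibus
tests with effect sizes, and post-hoc procedures.

Decision tree per variable:

1. normality per group — Shapiro-Wilk when the group has n < 50, otherwise
   Lilliefors-style Kolmogorov-Smirnov; any non-normal group sends the
   variable to Kruskal-Wallis;
2. homoscedasticity — Levene's test on the (all-normal) groups; violation
   sends the variable to Welch's ANOVA, otherwise classical one-way ANOVA.

Effect sizes: eta-squared (SS_between / SS_total) for ANOVA/Welch, epsilon-
squared H*(n+1)/(n^2-1) for Kruskal-Wallis, labelled small/medium/large at
the 0.01/0.06/0.14 thresholds.  Post hoc: Games-Howell after ANOVA/Welch,
Dunn's rank test (Holm-adjusted by default) after Kruskal-Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.05
EFFECT_THRESHOLDS = (0.01, 0.06, 0.14)  # small / medium / large


class DegenerateDataError(ValueError):
    """The data cannot support the requested test (constant or too small)."""


@dataclass
class TestSelection:
    test: str  # "anova" | "welch" | "kruskal_wallis"
    normality_p: dict[str, float]
    levene_p: float | None


@dataclass
class GroupComparison:
    variable: str
    test_used: str
    statistic: float
    p_value: float
    effect_size: float
    effect_metric: str  # "eta_squared" | "epsilon_squared"
    effect_label: str
    posthoc: pd.DataFrame | None = None
    posthoc_method: str | None = None
    ordering: str = ""
    diagnostics: TestSelection | None = None
    group_means: dict[str, float] = field(default_factory=dict)


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = ((f"g{i}", g) for i, g in enumerate(groups))
    out = {str(k): np.asarray(v, float) for k, v in items}
    if len(out) < 2:
        raise DegenerateDataError("need at least 2 groups")
    return out


def select_test(groups, alpha: float = ALPHA_DEFAULT) -> TestSelection:
    """Choose among ANOVA, Welch's ANOVA and Kruskal-Wallis from the data."""
    gd = _as_groups(groups)
    norm_p: dict[str, float] = {}
    for name, x in gd.items():
        if x.size < 3:
            raise DegenerateDataError(f"group {name!r} has n < 3")
        if np.std(x, ddof=1) == 0:
            norm_p[name] = 0.0  # a constant group is trivially non-normal
            continue
        if x.size < 50:
            norm_p[name] = float(stats.shapiro(x).pvalue)
        else:
            z = (x - x.mean()) / x.std(ddof=1)
            norm_p[name] = float(stats.kstest(z, "norm").pvalue)
    if any(p < alpha for p in norm_p.values()):
        return TestSelection("kruskal_wallis", norm_p, None)
    lev = float(stats.levene(*gd.values(), center="median").pvalue)
    if lev < alpha:
        return TestSelection("welch", norm_p, lev)
    return TestSelection("anova", norm_p, lev)


def eta_squared(groups) -> float:
    """Eta-squared from sums of squares: SS_between / SS_total."""
    gd = _as_groups(groups)
    allv = np.concatenate(list(gd.values()))
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    if ss_total == 0:
        raise DegenerateDataError("constant data: SS_total is zero")
    ss_between = float(sum(x.size * (x.mean() - grand) ** 2 for x in gd.values()))
    return ss_between / ss_total


def eta_squared_from_f_effect(f: float) -> float:
    """Convert Cohen's f to eta-squared: f^2 / (1 + f^2)."""
    return f**2 / (1.0 + f**2)


def epsilon_squared(h: float, n: int) -> float:
    """Epsilon-squared effect size for a Kruskal-Wallis H at total size n."""
    return h * (n + 1) / (n**2 - 1)


def omnibus(groups, test: str) -> tuple[float, float, float]:
    """Run the chosen omnibus test; returns (statistic, p, effect size).

    Effect size is eta-squared for "anova"/"welch" and epsilon-squared for
    "kruskal_wallis".
    """
    gd = _as_groups(groups)
    allv = np.concatenate(list(gd.values()))
    if np.std(allv) == 0:
        raise DegenerateDataError("constant data")
    if test == "anova":
        res = stats.f_oneway(*gd.values())
        return float(res.statistic), float(res.pvalue), eta_squared(gd)
    if test == "welch":
        import pingouin as pg

        long = pd.DataFrame(
            {
                "value": allv,
                "group": np.concatenate(
                    [np.full(x.size, name) for name, x in gd.items()]
                ),
            }
        )
        aov = pg.welch_anova(data=long, dv="value", between="group")
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        return float(aov["F"].iloc[0]), float(aov[pcol].iloc[0]), eta_squared(gd)
    if test == "kruskal_wallis":
        res = stats.kruskal(*gd.values())
        h = float(res.statistic)
        return h, float(res.pvalue), epsilon_squared(h, allv.size)
    raise ValueError(f"unknown test {test!r}")


def effect_label(value: float, metric: str = "eta_squared") -> str:
    """Cohen-style magnitude label at the 0.01 / 0.06 / 0.14 thresholds."""
    small, medium, large = EFFECT_THRESHOLDS
    if value < medium:
        return "small"
    if value < large:
        return "medium"
    return "large"


def games_howell(groups) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (unequal variances).

    Studentized-range p-values with Welch-Satterthwaite degrees of freedom per
    pair; returns a symmetric position-by-position matrix of p-values.
    """
    gd = _as_groups(groups)
    names = list(gd)
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    k = len(names)
    for a, b in combinations(names, 2):
        x, y = gd[a], gd[b]
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        se = np.sqrt(vx + vy)
        if se == 0:
            pv = 1.0
        else:
            t = abs(x.mean() - y.mean()) / se
            df = (vx + vy) ** 2 / (
                vx**2 / (x.size - 1) + vy**2 / (y.size - 1)
            )
            pv = float(stats.studentized_range.sf(t * np.sqrt(2.0), k, df))
        p.loc[a, b] = p.loc[b, a] = min(pv, 1.0)
    return p


def dunn(groups, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal-Wallis.

    Pairwise Z statistics on pooled mean ranks with tie correction;
    family-wise adjustment is "holm" (default), "bonferroni" or "none".
    Returns a symmetric matrix of adjusted p-values.
    """
    from statsmodels.stats.multitest import multipletests

    gd = _as_groups(groups)
    names = list(gd)
    allv = np.concatenate(list(gd.values()))
    n = allv.size
    ranks = stats.rankdata(allv)
    mean_ranks: dict[str, float] = {}
    start = 0
    for name, x in gd.items():
        mean_ranks[name] = float(ranks[start:start + x.size].mean())
        start += x.size
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    pairs = list(combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / gd[a].size + 1.0 / gd[b].size))
        if se == 0:
            raw.append(1.0)
            continue
        z = abs(mean_ranks[a] - mean_ranks[b]) / se
        raw.append(float(2.0 * stats.norm.sf(z)))
    if adjust == "none":
        adj = raw
    elif adjust in ("holm", "bonferroni"):
        adj = multipletests(raw, method=adjust)[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), pv in zip(pairs, adj):
        p.loc[a, b] = p.loc[b, a] = float(min(pv, 1.0))
    return p


def ordering_string(group_means: dict[str, float], posthoc: pd.DataFrame | None,
                    alpha: float = ALPHA_DEFAULT) -> str:
    """Compact ordering such as "OL>DL=LB>Rest" from means and pairwise p.

    Groups are sorted by mean (descending) and greedily clustered: a group
    joins the current block when it is not significantly different from every
    member of that block.  A trailing block of three or more groups is
    rendered as "Rest".
    """
    names = sorted(group_means, key=group_means.__getitem__, reverse=True)
    if posthoc is None:
        return "ns"
    blocks: list[list[str]] = [[names[0]]]
    for name in names[1:]:
        if all(posthoc.loc[name, other] >= alpha for other in blocks[-1]):
            blocks[-1].append(name)
        else:
            blocks.append([name])
    if len(blocks) == 1:
        return "ns"
    rendered = ["=".join(b) for b in blocks]
    if len(blocks[-1]) >= 3:
        rendered[-1] = "Rest"
    return ">".join(rendered)


def compare_groups(variable: str, groups, alpha: float = ALPHA_DEFAULT,
                   dunn_adjust: str = "holm") -> GroupComparison:
    """Full battery for one variable: select test, omnibus, effect, post hoc."""
    gd = _as_groups(groups)
    sel = select_test(gd, alpha=alpha)
    statistic, p, es = omnibus(gd, sel.test)
    metric = "epsilon_squared" if sel.test == "kruskal_wallis" else "eta_squared"
    means = {k: float(v.mean()) for k, v in gd.items()}
    posthoc = None
    method = None
    ordering = "ns"
    if p < alpha:
        if sel.test == "kruskal_wallis":
            posthoc, method = dunn(gd, adjust=dunn_adjust), "dunn"
        else:
            posthoc, method = games_howell(gd), "games_howell"
        ordering = ordering_string(means, posthoc, alpha=alpha)
    return GroupComparison(
        variable=variable,
        test_used=sel.test,
        statistic=statistic,
        p_value=p,
        effect_size=es,
        effect_metric=metric,
        effect_label=effect_label(es, metric),
        posthoc=posthoc,
        posthoc_method=method,
        ordering=ordering,
        diagnostics=sel,
        group_means=means,
    )


def compare_all(df: pd.DataFrame, variables, group_col: str = "position",
                alpha: float = ALPHA_DEFAULT,
                dunn_adjust: str = "holm") -> list[GroupComparison]:
    """Apply :func:`compare_groups` to each variable of a long-format table."""
    out = []
    for v in variables:
        groups = {
            str(g): sub[v].to_numpy(float) for g, sub in df.groupby(group_col)
        }
        out.append(compare_groups(v, groups, alpha=alpha, dunn_adjust=dunn_adjust))
    return out


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flat summary table (one row per variable) for reporting."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "variable": c.variable,
                "test": c.test_used,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "effect_metric": c.effect_metric,
                "effect_size": c.effect_size,
                "effect_label": c.effect_label,
                "posthoc": c.posthoc_method or "",
                "ordering": c.ordering,
            }
        )
    return pd.DataFrame(rows)
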