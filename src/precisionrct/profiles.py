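"""Baseline characterization of ITR-assigned subgroups with multiplicity
control (the descriptive-table machinery).

Continuous variables are summarized as mean (SD) and compared by one-way
ANOVA; right-skewed variables (e.g. hypoglycemia episode counts) as median
(IQR) with Kruskal-Wallis; categorical variables as n (%) with a Pearson
chi-square on the contingency table, switching to an exact/Monte-Carlo
Fisher test when any expected cell count falls below 5.  Pairwise tests
compare each group against the intervention group (Welch t, rank-sum, or
chi-square/Fisher).  Raw p values are adjusted by the Benjamini-Hochberg
step-up procedure, which controls the false discovery rate; two-tailed
alpha = 0.05 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import CONTROL, INTERVENTION, MUTED

logger = logging.getLogger(__name__)

__all__ = [
    "Variable",
    "TestResult",
    "summarize_by_group",
    "omnibus_test",
    "pairwise_tests",
    "bh_adjust",
    "profile_report",
]

#: display order of the ITR-assigned groups
GROUP_ORDER = (INTERVENTION, MUTED, CONTROL)

_FISHER_MC_DRAWS = 20_000


@dataclass(frozen=True)
class Variable:
    """Schema entry: the kind decides summary statistic and admissible test.

    kind: 'continuous' (mean/SD, ANOVA, Welch t), 'skewed' (median/IQR,
    Kruskal-Wallis, rank-sum) or 'categorical' (n (%), chi-square/Fisher).
    """

    name: str
    kind: str
    categories: tuple = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "skewed", "categorical"):
            raise ValueError(f"variable {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class TestResult:
    variable: str
    test: str
    statistic: float
    df: float | None
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None
    comparison: str = "omnibus"


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation quantile convention; IQR values depend on it
    q1, med, q3 = np.percentile(x, (25, 50, 75))
    return float(q1), float(med), float(q3)


def summarize_by_group(table, labels, schema: list[Variable]) -> pd.DataFrame:
    """Descriptive summary per ITR-assigned group (Table-3-style layout).

    Returns one row per variable (per category for categorical variables)
    and one formatted-string column per group in the order intervention,
    muted, control.  Empty groups yield NA columns with a warning.
    """
    df = table.df if hasattr(table, "df") else table
    labels = np.asarray(labels)
    groups = [g for g in GROUP_ORDER]
    rows = []
    for var in schema:
        x_all = df[var.name]
        entry: dict[str, object] = {"variable": var.name}
        if var.kind == "categorical":
            cats = var.categories or tuple(np.unique(x_all.dropna()))
            for cat in cats:
                crow = {"variable": f"{var.name}={cat}"}
                for g in groups:
                    xg = x_all[labels == g].dropna()
                    if len(xg) == 0:
                        logger.warning("empty group %s for %s", g, var.name)
                        crow[g] = "NA"
                        continue
                    k = int((xg == cat).sum())
                    crow[g] = f"{k} ({100.0 * k / len(xg):.1f}%)"
                rows.append(crow)
            continue
        for g in groups:
            xg = x_all[labels == g].dropna().to_numpy(dtype=float)
            if len(xg) == 0:
                logger.warning("empty group %s for %s", g, var.name)
                entry[g] = "NA"
            elif var.kind == "continuous":
                sd = xg.std(ddof=1) if len(xg) > 1 else 0.0
                entry[g] = f"{xg.mean():.2f} ({sd:.2f})"
            else:  # skewed
                q1, med, q3 = _quartiles(xg)
                entry[g] = f"{med:g} ({q1:g}-{q3:g})"
        rows.append(entry)
    return pd.DataFrame(rows)


def _contingency(values: np.ndarray, labels: np.ndarray, group_names) -> np.ndarray:
    cats = np.unique(values)
    return np.array(
        [[(values[labels == g] == c).sum() for g in group_names] for c in cats],
        dtype=float,
    )


def _categorical_test(tab: np.ndarray, rng=None) -> TestResult:
    """Pearson chi-square without continuity correction; Fisher fallback
    (exact for 2x2, Monte Carlo with fixed margins otherwise) when any
    expected count is below 5."""
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return TestResult("", "chi-square", 0.0, 0.0, 1.0)
    chi2, p, dof, expected = stats.chi2_contingency(tab, correction=False)
    if (expected >= 5).all():
        return TestResult("", "chi-square", float(chi2), float(dof), float(p))
    if tab.shape == (2, 2):
        logger.info("expected count < 5: Fisher exact test")
        _, p = stats.fisher_exact(tab.astype(int))
        return TestResult("", "fisher-exact", float("nan"), None, float(p))
    logger.info("expected count < 5 on r x c table: Monte-Carlo Fisher test")
    rng = rng or np.random.default_rng(0)
    dist = stats.random_table(tab.sum(axis=1), tab.sum(axis=0))
    draws = dist.rvs(_FISHER_MC_DRAWS, random_state=rng)
    colsum = tab.sum(axis=0)
    rowsum = tab.sum(axis=1)
    exp = np.outer(rowsum, colsum) / tab.sum()
    stat_obs = ((tab - exp) ** 2 / exp).sum()
    stat_draws = ((draws - exp) ** 2 / exp).sum(axis=(1, 2))
    p_mc = (1.0 + (stat_draws >= stat_obs - 1e-9).sum()) / (1.0 + _FISHER_MC_DRAWS)
    return TestResult("", "fisher-mc", float(stat_obs), None, float(min(p_mc, 1.0)))


def omnibus_test(values, labels, kind: str, rng=None) -> TestResult:
    """Across-group omnibus test chosen by variable kind.

    continuous -> one-way ANOVA; skewed -> Kruskal-Wallis; categorical ->
    Pearson chi-square (Fisher fallback when any expected count < 5).
    All-identical values yield p = 1 by convention.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    ok = ~pd.isna(values)
    values, labels = values[ok], labels[ok]
    group_names = [g for g in GROUP_ORDER if np.any(labels == g)]
    if len(group_names) < 2:
        raise ValueError("omnibus_test requires at least two non-empty groups")
    if kind == "categorical":
        res = _categorical_test(_contingency(values, labels, group_names), rng)
        return res
    samples = [values[labels == g].astype(float) for g in group_names]
    if len(np.unique(values.astype(float))) < 2:
        return TestResult("", "anova" if kind == "continuous" else "kruskal", 0.0, None, 1.0)
    if kind == "continuous":
        stat, p = stats.f_oneway(*samples)
        df1 = len(samples) - 1
        df2 = sum(len(s) for s in samples) - len(samples)
        if np.isnan(stat):  # zero within-group variance everywhere
            stat, p = np.inf, 0.0
        return TestResult("", "anova", float(stat), float(df1), float(p))
    if kind == "skewed":
        stat, p = stats.kruskal(*samples)
        return TestResult("", "kruskal", float(stat), float(len(samples) - 1), float(p))
    raise ValueError(f"unknown variable kind {kind!r}")


def pairwise_tests(
    values, labels, kind: str, reference_group: str = INTERVENTION, rng=None
) -> list[TestResult]:
    """Each non-reference group against the reference (intervention) group.

    continuous -> Welch two-sample t; skewed -> Wilcoxon rank-sum
    (Mann-Whitney); categorical -> chi-square with Fisher fallback.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    ok = ~pd.isna(values)
    values, labels = values[ok], labels[ok]
    if not np.any(labels == reference_group):
        logger.warning("reference group %r is empty; no pairwise tests", reference_group)
        return []
    results = []
    for g in GROUP_ORDER:
        if g == reference_group or not np.any(labels == g):
            continue
        pair = np.isin(labels, (reference_group, g))
        v, l = values[pair], labels[pair]
        if kind == "categorical":
            res = _categorical_test(_contingency(v, l, [reference_group, g]), rng)
        else:
            a = v[l == reference_group].astype(float)
            b = v[l == g].astype(float)
            if len(np.unique(np.concatenate([a, b]))) < 2:
                res = TestResult("", "t-welch" if kind == "continuous" else "ranksum",
                                 0.0, None, 1.0)
            elif kind == "continuous":
                stat, p = stats.ttest_ind(a, b, equal_var=False)
                res = TestResult("", "t-welch", float(stat), None, float(p))
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                res = TestResult("", "ranksum", float(stat), None, float(p))
        res.comparison = f"{g} vs {reference_group}"
        results.append(res)
    return results


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(p_adjusted, reject)`` in the input order, with
    adjusted_(i) = min_{j >= i} min(1, m p_(j) / j) over the ascending sort.
    Rejections are where the adjusted p value is <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj <= alpha


def profile_report(
    table,
    labels,
    schema: list[Variable],
    alpha: float = 0.05,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full subgroup profile: descriptive summary plus BH-adjusted tests.

    The omnibus p values of all schema variables form one BH family; the
    pairwise p values form a second family.  Returns ``(summary, tests)``
    DataFrames.
    """
    df = table.df if hasattr(table, "df") else table
    labels = np.asarray(labels)
    summary = summarize_by_group(table, labels, schema)
    results: list[TestResult] = []
    n_groups = sum(np.any(labels == g) for g in GROUP_ORDER)
    if n_groups < 2:
        logger.warning("fewer than two non-empty groups; no tests computed")
        return summary, pd.DataFrame()
    for var in schema:
        kind = "categorical" if var.kind == "categorical" else var.kind
        res = omnibus_test(df[var.name], labels, kind, rng)
        res.variable = var.name
        results.append(res)
        for pres in pairwise_tests(df[var.name], labels, kind, rng=rng):
            pres.variable = var.name
            results.append(pres)
    for family in ("omnibus", "pairwise"):
        fam = [r for r in results if (r.comparison == "omnibus") == (family == "omnibus")]
        if not fam:
            continue
        adj, rej = bh_adjust([r.p_raw for r in fam], alpha)
        for r, a, s in zip(fam, adj, rej):
            r.p_adjusted = float(a)
            r.significant = bool(s)
    tests = pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "comparison": [r.comparison for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )
    return summary, tests
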