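"""Group-comparison statistics with the two-control significance rule.

Each experimental (Gal4 > UAS) group is compared against both parental
controls (Gal4/+ and UAS/+); an effect counts as significant only when the
test group differs from *both* controls. Test selection follows a normality
gate: D'Agostino-Pearson for groups of n >= 8, Shapiro-Wilk for smaller
groups; all groups normal -> parametric branch (one-way ANOVA with Dunnett's
post hoc against the test group, Sidak-adjusted pairwise t-tests as an
option), otherwise Kruskal-Wallis with Dunn's post hoc test.

Dunn's test is the standard rank-based z comparison with tie correction and
Bonferroni adjustment over the comparisons performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "normality_gate",
    "two_control_comparison",
    "compare_two",
    "summary_table",
    "DEFAULT_ALPHA",
    "SHAPIRO_MAX_N",
]

DEFAULT_ALPHA = 0.05
#: Groups smaller than this use Shapiro-Wilk instead of D'Agostino-Pearson.
SHAPIRO_MAX_N = 8


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")


@dataclass
class ComparisonResult:
    metric: str
    condition: str
    test_name: str
    p_vs_control1: float
    p_vs_control2: float
    overall_significant: bool
    alpha: float
    branch: str  # "parametric" | "nonparametric"
    omnibus_p: float = float("nan")
    degenerate: bool = False


def normality_gate(samples: Sequence[GroupSample], alpha: float = DEFAULT_ALPHA) -> str:
    """Decide the test branch from per-group normality tests.

    Returns "parametric" iff every group passes its normality test at
    ``alpha`` (D'Agostino-Pearson for n >= SHAPIRO_MAX_N, Shapiro-Wilk for
    smaller groups), else "nonparametric".
    """
    for g in samples:
        n = len(g.values)
        if n < 3:
            raise ValueError(f"group {g.label!r} has n={n} < 3")
        if np.ptp(g.values) == 0.0:
            return "nonparametric"  # constant data: normality undefined
        if n >= SHAPIRO_MAX_N:
            _, p = stats.normaltest(g.values)
        else:
            _, p = stats.shapiro(g.values)
        if p < alpha:
            return "nonparametric"
    return "parametric"


def _dunn_pvalues(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Dunn's post hoc z-test of group 0 against each other group.

    Mean-rank differences scaled by the tie-corrected null variance;
    two-sided p-values Bonferroni-adjusted for the number of comparisons.
    """
    all_vals = np.concatenate(groups)
    n_tot = len(all_vals)
    ranks = stats.rankdata(all_vals)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        float(np.mean(ranks[bounds[i]:bounds[i + 1]])) for i in range(len(groups))
    ]
    m = len(groups) - 1
    pvals = []
    for j in range(1, len(groups)):
        se = math.sqrt(var_base * (1.0 / len(groups[0]) + 1.0 / len(groups[j])))
        if se == 0.0:
            pvals.append(1.0)
            continue
        z = (mean_ranks[0] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        pvals.append(min(1.0, p * m))
    return np.asarray(pvals)


def two_control_comparison(
    test: GroupSample,
    ctrl1: GroupSample,
    ctrl2: GroupSample,
    metric: str = "",
    alpha: float = DEFAULT_ALPHA,
    branch: Optional[str] = None,
    parametric_posthoc: str = "dunnett",
) -> ComparisonResult:
    """Compare a test group against both parental controls.

    ``branch`` forces "parametric"/"nonparametric"; by default the normality
    gate decides. Overall significance requires both adjusted p-values below
    ``alpha``.
    """
    groups = [test, ctrl1, ctrl2]
    values = [g.values for g in groups]
    if branch is None:
        branch = normality_gate(groups, alpha)
    if branch not in ("parametric", "nonparametric"):
        raise ValueError("branch must be 'parametric' or 'nonparametric'")

    if np.ptp(np.concatenate(values)) == 0.0:
        # all values identical across all groups: nothing to test
        return ComparisonResult(
            metric=metric, condition=test.label, test_name="degenerate",
            p_vs_control1=1.0, p_vs_control2=1.0, overall_significant=False,
            alpha=alpha, branch=branch, degenerate=True,
        )

    if branch == "parametric":
        _, omnibus_p = stats.f_oneway(*values)
        if parametric_posthoc == "dunnett":
            res = stats.dunnett(ctrl1.values, ctrl2.values, control=test.values)
            p1, p2 = float(res.pvalue[0]), float(res.pvalue[1])
            test_name = "ANOVA + Dunnett"
        elif parametric_posthoc == "sidak":
            raw = [
                stats.ttest_ind(test.values, c.values).pvalue
                for c in (ctrl1, ctrl2)
            ]
            p1, p2 = (1.0 - (1.0 - float(p)) ** 2 for p in raw)
            test_name = "ANOVA + Sidak t"
        else:
            raise ValueError("parametric_posthoc must be 'dunnett' or 'sidak'")
    else:
        _, omnibus_p = stats.kruskal(*values)
        p1, p2 = (float(p) for p in _dunn_pvalues(values))
        test_name = "Kruskal-Wallis + Dunn"

    return ComparisonResult(
        metric=metric, condition=test.label, test_name=test_name,
        p_vs_control1=p1, p_vs_control2=p2,
        overall_significant=bool(p1 < alpha and p2 < alpha),
        alpha=alpha, branch=branch, omnibus_p=float(omnibus_p),
    )


def compare_two(
    a: GroupSample,
    b: GroupSample,
    metric: str = "",
    alpha: float = DEFAULT_ALPHA,
    branch: Optional[str] = None,
) -> ComparisonResult:
    """Two-sample comparison (e.g. 25 vs 31 degC wild type).

    t-test on the parametric branch, Mann-Whitney otherwise; reported in the
    same result record with both control slots holding the single p-value.
    """
    if branch is None:
        branch = normality_gate([a, b], alpha)
    if np.ptp(np.concatenate([a.values, b.values])) == 0.0:
        return ComparisonResult(
            metric=metric, condition=f"{a.label} vs {b.label}",
            test_name="degenerate", p_vs_control1=1.0, p_vs_control2=1.0,
            overall_significant=False, alpha=alpha, branch=branch,
            degenerate=True,
        )
    if branch == "parametric":
        _, p = stats.ttest_ind(a.values, b.values)
        name = "t-test"
    else:
        _, p = stats.mannwhitneyu(a.values, b.values, alternative="two-sided")
        name = "Mann-Whitney"
    p = float(p)
    return ComparisonResult(
        metric=metric, condition=f"{a.label} vs {b.label}", test_name=name,
        p_vs_control1=p, p_vs_control2=p,
        overall_significant=bool(p < alpha), alpha=alpha, branch=branch,
        omnibus_p=p,
    )


def summary_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """One row per (condition, metric) comparison, reproducibly ordered."""
    if not results:
        raise ValueError("no comparisons to tabulate")
    rows = [
        {
            "condition": r.condition,
            "metric": r.metric,
            "branch": r.branch,
            "test": r.test_name,
            "omnibus_p": r.omnibus_p,
            "p_vs_control1": r.p_vs_control1,
            "p_vs_control2": r.p_vs_control2,
            "significant": r.overall_significant,
            "alpha": r.alpha,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["condition", "metric"], kind="stable").reset_index(drop=True)
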