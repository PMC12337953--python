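"""Cross-proteome inference: ANOVA, Tukey HSD, pairwise Welch t, Pearson χ².

Thin, validated wrappers around the classical scipy/statsmodels routines,
returning typed results with the degrees of freedom spelled out. The χ²
contingency test is the plain Pearson statistic — no continuity or
small-expected-count correction — with dof = (r − 1)(c − 1), as used for
proteome × quadrant tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "ContingencyResult",
    "one_way_anova",
    "tukey_hsd",
    "pairwise_t",
    "chi_squared_test",
]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    dof: int
    p_value: float
    expected: np.ndarray


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over two or more groups."""
    arrays = _check_groups(groups)
    n_total = sum(g.size for g in arrays)
    k = len(arrays)
    pooled = np.concatenate(arrays)
    ssb = sum(g.size * (g.mean() - pooled.mean()) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ssb == 0.0 and ssw == 0.0:
        raise ValueError("zero between- and within-group variance")
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(
        f_stat=float(f), df_between=k - 1, df_within=n_total - k, p_value=float(p)
    )


def _labels(groups: Sequence, labels: Sequence[str] | None) -> list[str]:
    if labels is None:
        return [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("one label per group required")
    return list(labels)


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """All pairwise mean differences with studentized-range adjusted p-values.

    Returns a long-format table with one row per unordered pair:
    (group_a, group_b, mean_diff, p_adj, ci_low, ci_high), where
    mean_diff = mean(a) − mean(b).
    """
    arrays = _check_groups(groups)
    names = _labels(groups, labels)
    res = sps.tukey_hsd(*arrays)
    ci = res.confidence_interval()
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        rows.append(
            (
                names[i],
                names[j],
                float(res.statistic[i, j]),
                float(res.pvalue[i, j]),
                float(ci.low[i, j]),
                float(ci.high[i, j]),
            )
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_diff", "p_adj", "ci_low", "ci_high"]
    )


def pairwise_t(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    correction: str | None = None,
) -> pd.DataFrame:
    """Pairwise Welch two-sample t-tests.

    *correction* is None (default, matching reporting that leaves multiple
    testing unadjusted), ``"bonferroni"`` or ``"holm"``. Degenerate pairs
    (both groups constant) raise.
    """
    arrays = _check_groups(groups)
    names = _labels(groups, labels)
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        a, b = arrays[i], arrays[j]
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                raise ValueError(
                    f"degenerate variance in pair ({names[i]}, {names[j]})"
                )
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append((names[i], names[j], float(a.mean() - b.mean()), float(t), float(p)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "t", "p"])
    if correction is not None:
        if correction not in ("bonferroni", "holm"):
            raise ValueError("correction must be None, 'bonferroni' or 'holm'")
        df["p_adj"] = multipletests(df["p"], method=correction)[1]
    return df


def chi_squared_test(table: np.ndarray | pd.DataFrame) -> ContingencyResult:
    """Pearson χ² test of independence on an r×c count table.

    Expected counts E_ij = (row_i · col_j)/N; χ² = Σ (O − E)²/E with
    dof = (r − 1)(c − 1); no continuity correction. Requires non-negative
    counts and strictly positive row and column sums.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an r×c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("every row and column must have a positive sum")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    return ContingencyResult(
        chi2=float(chi2), dof=int(dof), p_value=float(p), expected=expected
    )
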