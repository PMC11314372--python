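"""Group comparison of physicochemical parameters.

Two-sided pooled-variance Student's t-test preceded by Shapiro–Wilk
normality checks per group and Levene's test for variance homogeneity.
Assumption violations are flagged, not acted on — the comparison stays a
Student's t (a Welch variant is available by flag). No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatReport:
    """One parameter, one grouping, one t-test with assumption checks."""

    parameter: str
    grouping: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_value: float
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    levene_p: float | None
    assumptions_ok: bool


def _shapiro_p(x: np.ndarray) -> float | None:
    if len(np.unique(x)) < 2 or len(x) < 3:
        return None  # constant or tiny sample: normality test undefined
    return float(sps.shapiro(x).pvalue)


def compare_groups(values_a, values_b, parameter: str = "value",
                   grouping: str = "group1_vs_group2",
                   alpha_assume: float = 0.05, welch: bool = False) -> StatReport:
    """Student's t comparison of one parameter between two groups.

    ``assumptions_ok`` is true iff both Shapiro p-values and the Levene
    p-value are defined and above ``alpha_assume``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 members")
    sh_a, sh_b = _shapiro_p(a), _shapiro_p(b)
    try:
        lev = float(sps.levene(a, b).pvalue)
    except ValueError:
        lev = None
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else (len(a) + len(b) - 2)
    ok = all(p is not None and p > alpha_assume for p in (sh_a, sh_b, lev))
    return StatReport(
        parameter=parameter,
        grouping=grouping,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
        t_statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        shapiro_p_a=sh_a,
        shapiro_p_b=sh_b,
        levene_p=lev,
        assumptions_ok=ok,
    )


def compare_table(profile_table: pd.DataFrame, group_col: str,
                  parameters: list[str], alpha_assume: float = 0.05,
                  welch: bool = False) -> pd.DataFrame:
    """Run compare_groups for each parameter over a two-level grouping."""
    levels = sorted(profile_table[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"grouping column {group_col!r} must have 2 levels, "
                         f"found {levels}")
    rows = []
    for param in parameters:
        sub = profile_table[[group_col, param]].dropna()
        a = sub.loc[sub[group_col] == levels[0], param]
        b = sub.loc[sub[group_col] == levels[1], param]
        rep = compare_groups(a, b, parameter=param,
                             grouping=f"{levels[0]}_vs_{levels[1]}",
                             alpha_assume=alpha_assume, welch=welch)
        rows.append(vars(rep))
    return pd.DataFrame(rows)


def summarize_by_group(profile_table: pd.DataFrame, group_col: str,
                       parameters: list[str]) -> pd.DataFrame:
    """Mean, SD and n per group per parameter."""
    if profile_table.empty:
        raise ValueError("empty profile table")
    out = profile_table.groupby(group_col)[parameters].agg(["mean", "std", "count"])
    out.columns = [f"{p}_{s}" for p, s in out.columns]
    return out.reset_index()
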