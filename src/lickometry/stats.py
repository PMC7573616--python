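"""Statistical battery: t tests, split-plot (mixed) ANOVA, repeated-measures
ANOVA and Bonferroni-adjusted pairwise comparisons.

The mixed (split-plot) ANOVA has a between-subjects factor (treatment group)
and a within-subjects factor (e.g. stimulus concentration), each tested
against its own error stratum:

* between stratum:  group  vs  subjects-within-group
* within stratum:   level and group x level  vs  level x subject-within-group

with degrees of freedom (g-1), g(n-1), (l-1), (g-1)(l-1), g(n-1)(l-1) for a
balanced design of g groups, n subjects per group, l within levels.  The
design must be complete and balanced; unbalanced input raises rather than
imputing.  No sphericity correction is applied by default.

P-values are two-tailed from the central t (or F) distribution, kept at full
precision internally; :func:`format_p` renders them at 3 decimals with a
"<0.001" display floor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_tailed: float
    kind: str  # paired | unpaired | welch
    n1: int
    n2: int


def t_p_two_tailed(t: float, df: float) -> float:
    """Two-tailed p-value for a t statistic: 2 * (1 - F_t(|t|; df))."""
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * sps.t.sf(abs(t), df))


def format_p(p: float, decimals: int = 3) -> str:
    """Display convention: 3-decimal rounding with a '<0.001' floor."""
    floor = 10.0 ** (-decimals)
    if p < floor:
        return f"<{floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


def paired_t(x, y) -> TTestResult:
    """Two-tailed paired-sample t test.

    t = mean(d) / (sd(d) / sqrt(n)) on the paired differences d = x - y, with
    df = n - 1.  Pairing follows the order of the inputs; callers pairing
    across independent groups (as when treatment groups of different animals
    are compared pairwise by subject sort order) get a design warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    return TTestResult(
        t=t, df=df, p_two_tailed=t_p_two_tailed(t, df), kind="paired", n1=n, n2=n
    )


def unpaired_t(x, y, welch: bool = False) -> TTestResult:
    """Two-tailed two-sample t test (pooled-variance or Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            raise ValueError("zero variance in both groups")
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = float((x.mean() - y.mean()) / math.sqrt(se2))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        df = n1 + n2 - 2
        t = float((x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2)))
    return TTestResult(
        t=t,
        df=float(df),
        p_two_tailed=t_p_two_tailed(t, df),
        kind="welch" if welch else "unpaired",
        n1=n1,
        n2=n2,
    )


def _check_balanced(df: pd.DataFrame, subject: str, between: str, within: str) -> None:
    counts = df.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise ValueError("design not balanced: each subject needs each level exactly once")
    subj_group = df.groupby(subject, observed=True)[between].nunique()
    if (subj_group != 1).any():
        raise ValueError("a subject appears in more than one group")
    per_group = df.groupby(between, observed=True)[subject].nunique()
    if per_group.nunique() != 1:
        raise ValueError("design not balanced: unequal subjects per group")
    levels_per_subject = df.groupby(subject, observed=True)[within].nunique()
    if levels_per_subject.nunique() != 1:
        raise ValueError("design not complete: subjects measured at different level sets")


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: str = "level",
) -> pd.DataFrame:
    """Classical split-plot ANOVA on a tidy long table.

    Returns a table with one row per effect (group, subjects-within-group,
    level, group:level, level x subject-within-group) holding sum of squares,
    df, mean square, F and p.  F is NaN (flagged) when its error mean square
    is zero.  The sums of squares of the five rows add up to the total SS.
    """
    df = data[[subject, between, within, dv]].dropna()
    _check_balanced(df, subject, between, within)

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    g = df[between].nunique()
    l = df[within].nunique()
    n = df[subject].nunique() // g
    if g < 2 or l < 2:
        raise ValueError("need at least two groups and two within levels")

    subj_means = df.groupby(subject, observed=True)[dv].mean()
    group_means = df.groupby(between, observed=True)[dv].mean()
    level_means = df.groupby(within, observed=True)[dv].mean()
    cell_means = df.groupby([between, within], observed=True)[dv].mean()

    ss_between_subj = float(l * ((subj_means - grand) ** 2).sum())
    ss_group = float(n * l * ((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group

    ss_level = float(g * n * ((level_means - grand) ** 2).sum())
    inter_dev = (
        cell_means
        - group_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - level_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_inter = float(n * (inter_dev**2).sum())
    ss_error_within = ss_total - ss_between_subj - ss_level - ss_inter

    rows = []

    def effect(name, ss, dfree, err_ss, err_df):
        ss = max(ss, 0.0)
        ms = ss / dfree
        err_ms = max(err_ss, 0.0) / err_df
        if err_ms > 0:
            F = ms / err_ms
            p = float(sps.f.sf(F, dfree, err_df))
        else:
            F, p = math.nan, math.nan
        rows.append(
            {"effect": name, "ss": ss, "df": dfree, "ms": ms, "F": F, "p": p}
        )

    df_group = g - 1
    df_subj = g * (n - 1)
    df_level = l - 1
    df_inter = (g - 1) * (l - 1)
    df_err = g * (n - 1) * (l - 1)

    effect(between, ss_group, df_group, ss_subj_within, df_subj)
    rows.append(
        {
            "effect": f"subjects_within_{between}",
            "ss": max(ss_subj_within, 0.0),
            "df": df_subj,
            "ms": max(ss_subj_within, 0.0) / df_subj,
            "F": math.nan,
            "p": math.nan,
        }
    )
    effect(within, ss_level, df_level, ss_error_within, df_err)
    effect(f"{between}:{within}", ss_inter, df_inter, ss_error_within, df_err)
    rows.append(
        {
            "effect": f"{within}_x_subjects_within_{between}",
            "ss": max(ss_error_within, 0.0),
            "df": df_err,
            "ms": max(ss_error_within, 0.0) / df_err,
            "F": math.nan,
            "p": math.nan,
        }
    )
    table = pd.DataFrame(rows)
    table.attrs["ss_total"] = ss_total
    return table


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "level",
) -> pd.DataFrame:
    """One-way repeated-measures ANOVA (within factor vs subject-by-level error)."""
    df = data[[subject, within, dv]].dropna()
    counts = df.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise ValueError("each subject needs each level exactly once")
    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    n = df[subject].nunique()
    l = df[within].nunique()
    subj_means = df.groupby(subject, observed=True)[dv].mean()
    level_means = df.groupby(within, observed=True)[dv].mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_subj = float(l * ((subj_means - grand) ** 2).sum())
    ss_level = float(n * ((level_means - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_level
    df_level, df_err = l - 1, (n - 1) * (l - 1)
    ms_level = ss_level / df_level
    ms_err = max(ss_err, 0.0) / df_err
    if ms_err > 0:
        F = ms_level / ms_err
        p = float(sps.f.sf(F, df_level, df_err))
    else:
        F, p = math.nan, math.nan
    return pd.DataFrame(
        [
            {"effect": within, "ss": ss_level, "df": df_level, "ms": ms_level, "F": F, "p": p},
            {"effect": "subjects", "ss": ss_subj, "df": n - 1, "ms": ss_subj / (n - 1), "F": math.nan, "p": math.nan},
            {"effect": "error", "ss": max(ss_err, 0.0), "df": df_err, "ms": ms_err, "F": math.nan, "p": math.nan},
        ]
    )


def bonferroni_adjust(p: float, family_size: int) -> float:
    """Bonferroni adjustment: min(1, p * family_size)."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return min(1.0, p * family_size)


def bonferroni_pairwise(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: str | None = "level",
    family_size: int | None = None,
    kind: str = "unpaired",
) -> pd.DataFrame:
    """Pairwise group comparisons at each within level, Bonferroni adjusted.

    The family is, by default, the number of pairwise tests conducted within
    the tastant (all group pairs at all levels); pass ``family_size`` to
    override.  The family size used is recorded in the output.
    """
    groups = sorted(data[between].unique())
    levels = sorted(data[within].unique()) if within else [None]
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    fam = family_size if family_size is not None else len(pairs) * len(levels)

    rows = []
    for level in levels:
        sub = data if level is None else data[data[within] == level]
        for a, b in pairs:
            xa = sub.loc[sub[between] == a].sort_values(subject)[dv].to_numpy()
            xb = sub.loc[sub[between] == b].sort_values(subject)[dv].to_numpy()
            if kind == "paired":
                if xa.size != xb.size:
                    raise ValueError("paired comparison requires equal group sizes")
                warnings.warn(
                    "pairing independent groups by subject sort order",
                    stacklevel=2,
                )
                res = paired_t(xa, xb)
            elif kind == "welch":
                res = unpaired_t(xa, xb, welch=True)
            else:
                res = unpaired_t(xa, xb)
            rows.append(
                {
                    "level": level,
                    "group_a": a,
                    "group_b": b,
                    "t": res.t,
                    "df": res.df,
                    "p_raw": res.p_two_tailed,
                    "p_adjusted": bonferroni_adjust(res.p_two_tailed, fam),
                    "family_size": fam,
                }
            )
    return pd.DataFrame(rows)
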