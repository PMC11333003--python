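"""Cohort reporting statistics: two-proportion Z, t-tests, ANOVA families.

Means are reported as mean +- SEM and binary metrics as proportion +- SEP
(``sqrt(p(1-p)/n)``).  Post-hoc families use Tukey (all pairs) or Dunnett
(vs control); no additional multiplicity layer is imposed on top.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateInputError(ValueError):
    pass


def sem(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


def sep(successes: int, n: int) -> float:
    """Standard error of a proportion."""
    p = successes / n
    return float(math.sqrt(p * (1 - p) / n))


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z-test; returns (z, two-sided p).

    Raises :class:`DegenerateInputError` when the pooled proportion is 0 or
    1 (zero pooled variance).
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("require 0 <= x <= n and n >= 1")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        raise DegenerateInputError("pooled proportion is 0 or 1")
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return z, float(2 * sps.norm.sf(abs(z)))


def _group_summary(df: pd.DataFrame, metric: str, group_col: str) -> dict:
    out = {}
    binary = df[metric].dropna().isin([0, 1, True, False]).all() and \
        df[metric].dtype != float
    for g, sub in df.groupby(group_col, sort=True):
        vals = sub[metric].dropna()
        if binary:
            x = int(vals.sum())
            out[str(g)] = {"proportion": x / len(vals),
                           "sep": sep(x, len(vals)), "n": len(vals)}
        else:
            out[str(g)] = {"mean": float(vals.mean()), "sem": sem(vals),
                           "n": len(vals)}
    return out


def group_tests(table: pd.DataFrame, metric: str, design: str,
                group_col: str = "genotype", control: str | None = None,
                factor2: str | None = None) -> dict:
    """Dispatch the cohort comparison prescribed by ``design``.

    designs: ``ttest`` (2 groups), ``anova_tukey`` (one-way + all-pairs
    Tukey), ``anova_dunnett`` (one-way + contrasts vs ``control``),
    ``two_way_anova`` (factors ``group_col`` and ``factor2``),
    ``two_proportion_z`` (binary metric, 2 groups).
    """
    df = table.dropna(subset=[metric])
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise DegenerateInputError("need at least 2 groups")
    samples = [df.loc[df[group_col] == g, metric].to_numpy(dtype=float)
               for g in groups]
    if any(len(s) < 2 for s in samples) and design != "two_proportion_z":
        raise DegenerateInputError("need >= 2 observations per group")
    report: dict = {"design": design, "metric": metric,
                    "groups": _group_summary(df, metric, group_col)}

    if design == "ttest":
        if len(groups) != 2:
            raise DegenerateInputError("t-test requires exactly 2 groups")
        t, p = sps.ttest_ind(samples[0], samples[1])
        report.update(statistic=float(t), p_value=float(p))
    elif design == "two_proportion_z":
        if len(groups) != 2:
            raise DegenerateInputError("Z-test requires exactly 2 groups")
        x = [int(np.sum(s)) for s in samples]
        n = [len(s) for s in samples]
        z, p = two_proportion_z(x[0], n[0], x[1], n[1])
        report.update(statistic=z, p_value=p)
    elif design in ("anova_tukey", "anova_dunnett"):
        F, p = sps.f_oneway(*samples)
        report.update(statistic=float(F), p_value=float(p))
        if design == "anova_tukey":
            res = sps.tukey_hsd(*samples)
            report["posthoc"] = {
                f"{groups[i]} vs {groups[j]}": {
                    "statistic": float(res.statistic[i, j]),
                    "p_value": float(res.pvalue[i, j])}
                for i in range(len(groups)) for j in range(len(groups))
                if i < j}
        else:
            if control is None:
                control = groups[0]
            ci = groups.index(control)
            others = [g for g in groups if g != control]
            res = sps.dunnett(*(samples[groups.index(g)] for g in others),
                              control=samples[ci])
            report["posthoc"] = {
                f"{g} vs {control}": {"statistic": float(res.statistic[k]),
                                      "p_value": float(res.pvalue[k])}
                for k, g in enumerate(others)}
    elif design == "two_way_anova":
        if factor2 is None:
            raise DegenerateInputError("two_way_anova requires factor2")
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        d = df.rename(columns={metric: "_y", group_col: "_g", factor2: "_f"})
        fit = smf.ols("_y ~ C(_g) + C(_f)", data=d).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        report.update(statistic=float(tab.loc["C(_g)", "F"]),
                      p_value=float(tab.loc["C(_g)", "PR(>F)"]),
                      factor2_F=float(tab.loc["C(_f)", "F"]),
                      factor2_p=float(tab.loc["C(_f)", "PR(>F)"]))
    else:
        raise ValueError(f"unknown design {design!r}")
    return report
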