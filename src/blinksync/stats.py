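"""Repeated-measures inference for blink counts and sigma-NCR tables.

One-way (and two-way with interaction) within-subject ANOVA by direct
sums-of-squares decomposition, with the generalized eta-squared effect size
(effect SS over effect SS plus all subject-related error SS).  Post hoc
pairwise comparisons are classical paired t-tests with Bonferroni adjustment
and pairwise confidence intervals mean_diff +/- t_{0.975,df} * SE_diff.
Sphericity is not corrected (reported df are the uncorrected ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RMAnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    generalized_eta2: float


def _pivot_balanced(table: pd.DataFrame, index: str, columns: list[str],
                    value: str = "value") -> pd.DataFrame:
    wide = table.pivot_table(index=index, columns=columns, values=value,
                             aggfunc="count")
    if wide.isna().any().any() or not (wide == 1).all().all():
        raise ValueError("unbalanced design: every participant needs exactly "
                         "one value per cell")
    return table.pivot_table(index=index, columns=columns, values=value)


def rm_anova(
    table: pd.DataFrame,
    factors: list[str] | str = "condition",
    subject: str = "participant",
    value: str = "value",
) -> list[RMAnovaResult]:
    """Within-subject ANOVA on a long-format balanced table.

    One factor gives the classical one-way repeated-measures F with error
    term the subject-by-factor interaction; two factors give main effects and
    the interaction, each tested against its own subject-by-effect error.
    Generalized eta^2 divides each effect SS by (effect SS + SS_subjects +
    all subject-interaction error SS).
    """
    if isinstance(factors, str):
        factors = [factors]
    if len(factors) not in (1, 2):
        raise ValueError("one or two within-subject factors supported")
    cols = [subject, *factors, value]
    df = table[cols].copy()
    _pivot_balanced(df, subject, factors, value)

    grand = df[value].mean()
    n_subj = df[subject].nunique()
    levels = {f: df[f].nunique() for f in factors}
    n_total = len(df)

    def ss_of(groupers: list[str]) -> float:
        means = df.groupby(groupers, observed=True)[value].mean()
        counts = df.groupby(groupers, observed=True)[value].count()
        return float((counts * (means - grand) ** 2).sum())

    ss_subject = ss_of([subject])
    ss_total = float(((df[value] - grand) ** 2).sum())
    tol = 1e-12 * (ss_total + 1e-300)

    def f_ratio(ss_eff: float, dfn: int, ss_err: float, dfe: int) -> float:
        # a design with no effect and no error variance has F = 0, not 0/0
        if ss_err <= tol:
            return 0.0 if ss_eff <= tol else float("inf")
        return (ss_eff / dfn) / (ss_err / dfe)

    results: list[RMAnovaResult] = []
    if len(factors) == 1:
        f = factors[0]
        k = levels[f]
        ss_effect = ss_of([f])
        ss_cells = ss_of([subject, f])
        ss_error = ss_cells - ss_subject - ss_effect
        df_num = k - 1
        df_den = (k - 1) * (n_subj - 1)
        F = f_ratio(ss_effect, df_num, ss_error, df_den)
        denom = ss_effect + ss_subject + ss_error
        eta_g = ss_effect / denom if denom > tol else 0.0
        p = float(sps.f.sf(F, df_num, df_den))
        results.append(RMAnovaResult(f, float(F), df_num, df_den, p, eta_g))
        return results

    fa, fb = factors
    a, b = levels[fa], levels[fb]
    ss_a = ss_of([fa])
    ss_b = ss_of([fb])
    ss_ab = ss_of([fa, fb]) - ss_a - ss_b
    ss_sa = ss_of([subject, fa]) - ss_subject - ss_a
    ss_sb = ss_of([subject, fb]) - ss_subject - ss_b
    ss_sab = (ss_total - ss_subject - ss_a - ss_b - ss_ab
              - ss_sa - ss_sb)
    err_all = ss_subject + ss_sa + ss_sb + ss_sab
    for name, ss_eff, dfn, ss_err, dfe in [
        (fa, ss_a, a - 1, ss_sa, (a - 1) * (n_subj - 1)),
        (fb, ss_b, b - 1, ss_sb, (b - 1) * (n_subj - 1)),
        (f"{fa}:{fb}", ss_ab, (a - 1) * (b - 1), ss_sab,
         (a - 1) * (b - 1) * (n_subj - 1)),
    ]:
        F = f_ratio(ss_eff, dfn, ss_err, dfe)
        p = float(sps.f.sf(F, dfn, dfe))
        denom = ss_eff + err_all
        eta_g = ss_eff / denom if denom > tol else 0.0
        results.append(RMAnovaResult(name, float(F), dfn, dfe, p, eta_g))
    return results


def paired_t_bonferroni(
    table: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    m: int | None = None,
    subject: str = "participant",
    condition: str = "condition",
    value: str = "value",
) -> pd.DataFrame:
    """Post hoc paired t-tests with Bonferroni adjustment and pairwise CIs.

    ``m`` defaults to the number of comparisons.  CI is the 95% pairwise
    interval mean_diff +/- t_{0.975,df} * SE(diff).
    """
    m = m if m is not None else len(comparisons)
    wide = table.pivot_table(index=subject, columns=condition, values=value)
    rows = []
    for c1, c2 in comparisons:
        pair = wide[[c1, c2]].dropna()
        n = len(pair)
        if n < 2:
            raise ValueError(f"comparison {c1} vs {c2}: fewer than 2 pairs")
        diff = pair[c1] - pair[c2]
        df = n - 1
        se = diff.std(ddof=1) / np.sqrt(n)
        md = float(diff.mean())
        if se == 0.0:
            # degenerate pairs: identical vectors test as "no difference"
            t = 0.0 if md == 0.0 else np.inf * np.sign(md)
            p_raw = 1.0 if md == 0.0 else 0.0
        else:
            t, p_raw = sps.ttest_rel(pair[c1], pair[c2])
        tcrit = sps.t.ppf(0.975, df)
        rows.append({
            "comparison": f"{c1} vs {c2}", "t": float(t), "df": df,
            "p_raw": float(p_raw), "p_adj": float(min(1.0, m * p_raw)),
            "mean_diff": md,
            "ci_low": md - tcrit * se, "ci_high": md + tcrit * se,
        })
    return pd.DataFrame(rows)


def remove_outliers_2sd(
    table: pd.DataFrame,
    subject: str = "participant",
    condition: str = "condition",
    value: str = "value",
    n_sd: float = 2.0,
) -> tuple[pd.DataFrame, list]:
    """Drop participants with any value beyond mean +/- n_sd SDs.

    The mean and SD are computed per condition across participants, with the
    candidate included; a participant flagged in at least one condition is
    removed entirely (all their rows).  Returns the filtered table and the
    removed participant list.
    """
    removed: set = set()
    for _, grp in table.groupby(condition, observed=True):
        if len(grp) < 3:
            raise ValueError("need >= 3 values per condition for the 2-SD rule")
        mu = grp[value].mean()
        sd = grp[value].std(ddof=1)
        flag = grp.loc[np.abs(grp[value] - mu) > n_sd * sd, subject]
        removed.update(flag.tolist())
    out = table[~table[subject].isin(removed)].copy()
    return out, sorted(removed)
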