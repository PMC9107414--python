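"""Between-group statistics on whole-brain summaries.

Compares per-subject scalars — whole-brain thin-patch fractions or mean CT
— across clinical groups: a one-way ANOVA, a covariate-adjusted linear
model (age + sex, partial F-test of the group factor), and Tukey HSD
post-hoc pairwise tests with age entered as a six-level categorical
covariate (the studentized-range adjustment only accommodates categorical
terms).

No Welch correction is applied; a warning is logged when the largest to
smallest group variance ratio exceeds 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.formula.api as smf

from .errors import DegenerateDataError

logger = logging.getLogger("mosaicct")

DEFAULT_AGE_BINS = 6


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adjusted: float


@dataclass
class GroupComparisonResult:
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def _as_frame(values: Sequence[float], groups: Sequence[str], **extra) -> pd.DataFrame:
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups), **extra})
    if df["value"].isna().any():
        raise DegenerateDataError("missing values in group comparison input")
    return df


def _check_variances(df: pd.DataFrame) -> None:
    v = df.groupby("group")["value"].var(ddof=1)
    if v.min() > 0 and v.max() / v.min() > 4:
        logger.warning(
            "group variance ratio %.1f exceeds 4; ANOVA assumes homoscedasticity", v.max() / v.min()
        )


def anova_oneway(values: Sequence[float], groups: Sequence[str]) -> GroupComparisonResult:
    """Classical one-way ANOVA (between/within decomposition, F = MSB/MSW)."""
    df = _as_frame(values, groups)
    sizes = df.groupby("group").size()
    if len(sizes) < 2:
        raise DegenerateDataError("need at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise DegenerateDataError(f"groups with < 2 subjects: {small}")
    _check_variances(df)
    samples = [g["value"].to_numpy() for _, g in df.groupby("group")]
    F, p = ss.f_oneway(*samples)
    k, n = len(sizes), len(df)
    if not np.isfinite(F):  # all-identical values: SSB = SSW = 0
        F, p = 0.0, 1.0
    return GroupComparisonResult(F=float(F), df_between=k - 1, df_within=n - k, p=float(p))


def ancova_adjusted(
    values: Sequence[float],
    groups: Sequence[str],
    age: Sequence[float],
    sex: Sequence[str],
) -> GroupComparisonResult:
    """Linear model value ~ group + age + sex; partial F-test of the group factor.

    The group effect is tested adjusted for both covariates (Type III-style
    marginal test).
    """
    df = _as_frame(values, groups, age=np.asarray(age, dtype=float), sex=list(sex))
    fit = smf.ols("value ~ C(group) + age + C(sex)", data=df).fit()
    if fit.model.exog.shape[1] > np.linalg.matrix_rank(fit.model.exog):
        names = list(fit.model.exog_names)
        raise DegenerateDataError(f"rank-deficient design matrix; columns: {names}")
    group_terms = [n for n in fit.model.exog_names if n.startswith("C(group)")]
    ftest = fit.f_test([f"{t} = 0" for t in group_terms])
    return GroupComparisonResult(
        F=float(ftest.fvalue),
        df_between=int(ftest.df_num),
        df_within=int(ftest.df_denom),
        p=float(ftest.pvalue),
    )


def bin_ages(age: Sequence[float], n_bins: int = DEFAULT_AGE_BINS, edges: Sequence[float] | None = None) -> pd.Categorical:
    """Convert age to a categorical covariate; default six equal-width bins
    over the pooled range (edges configurable)."""
    age = np.asarray(age, dtype=float)
    if edges is None:
        binned = pd.cut(age, bins=n_bins, include_lowest=True)
    else:
        binned = pd.cut(age, bins=list(edges), include_lowest=True)
    counts = binned.value_counts()
    empty = counts[counts == 0].index.tolist()
    if empty:
        logger.warning("empty age bins dropped from the design: %s", empty)
    return binned.remove_unused_categories()


def tukey_hsd(
    values: Sequence[float],
    groups: Sequence[str],
    age_bins: Sequence | None = None,
    sex: Sequence[str] | None = None,
) -> list[PairwiseResult]:
    """Tukey HSD pairwise group comparisons from a linear model.

    The model adjusts for the categorical covariates supplied (age bins,
    sex); pairwise differences of adjusted group means are referred to the
    studentized range distribution with k = number of groups and the model's
    residual degrees of freedom.  With exactly two groups and no covariates
    this reduces to the pooled two-sample t-test (q = √2·|t|).
    """
    extra = {}
    formula = "value ~ C(group)"
    if age_bins is not None:
        extra["age_bin"] = pd.Categorical(age_bins).remove_unused_categories()
        formula += " + C(age_bin)"
    if sex is not None:
        extra["sex"] = list(sex)
        formula += " + C(sex)"
    df = _as_frame(values, groups, **extra)
    levels = sorted(df["group"].unique())
    k = len(levels)
    if k < 2:
        raise DegenerateDataError("need at least 2 groups for pairwise comparisons")
    fit = smf.ols(formula, data=df).fit()
    dof = int(fit.df_resid)

    # adjusted group means: contrast on the group dummies (treatment coding,
    # covariates cancel in pairwise differences)
    names = fit.model.exog_names
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            c = np.zeros(len(names))
            term_a = f"C(group)[T.{a}]"
            term_b = f"C(group)[T.{b}]"
            # mean_diff convention: group_b minus group_a
            if term_b in names:
                c[names.index(term_b)] += 1.0
            if term_a in names:
                c[names.index(term_a)] -= 1.0
            diff = float(c @ fit.params)
            se = float(np.sqrt(c @ fit.cov_params() @ c))
            if se == 0:
                raise DegenerateDataError(f"zero standard error for contrast {a} vs {b}")
            q = np.sqrt(2.0) * abs(diff) / se
            p_adj = float(ss.studentized_range.sf(q, k, dof))
            out.append(PairwiseResult(group_a=a, group_b=b, mean_diff=diff, p_adjusted=min(p_adj, 1.0)))
    return out


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    age: Sequence[float] | None = None,
    sex: Sequence[str] | None = None,
    adjust_covariates: bool = False,
    n_age_bins: int = DEFAULT_AGE_BINS,
) -> GroupComparisonResult:
    """Omnibus test plus Tukey HSD post-hoc, as run on whole-brain summaries.

    ``adjust_covariates=False`` runs the plain one-way ANOVA (appropriate for
    thin-patch fractions, where matching already absorbs demographics);
    ``True`` runs the covariate-adjusted model (appropriate for raw mean CT).
    """
    if adjust_covariates:
        if age is None or sex is None:
            raise DegenerateDataError("covariate adjustment requires age and sex")
        res = ancova_adjusted(values, groups, age, sex)
    else:
        res = anova_oneway(values, groups)
    bins = bin_ages(age, n_bins=n_age_bins) if age is not None else None
    res.pairwise = tukey_hsd(values, groups, age_bins=bins, sex=sex)
    return res
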