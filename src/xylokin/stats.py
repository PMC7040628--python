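"""Group-level inference: one-way ANOVA with Tukey HSD, and linear
mixed-effects slopes of tracheid traits on differentiation durations.

Shapiro-Wilk and Levene checks are reported as diagnostics alongside the
ANOVA but never gate it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "MixedSlopeResult",
    "one_way_anova",
    "mixed_slope",
    "anova_to_frame",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    tukey: dict  # (group_a, group_b) -> (mean difference, adjusted p)
    shapiro_p: float = float("nan")  # residual normality diagnostic
    levene_p: float = float("nan")  # variance homogeneity diagnostic


@dataclass(frozen=True)
class MixedSlopeResult:
    slope: float
    intercept: float
    slope_ci: tuple
    tree_variance: float
    residual_variance: float


def one_way_anova(values_by_group: dict) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons.

    ``values_by_group`` maps group label -> sequence of per-tree values.
    The between/within decomposition is computed explicitly; adjusted
    pairwise p-values come from the studentized range distribution with the
    pooled within-group variance.
    """
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least two values")
    all_values = np.concatenate([data[g] for g in groups])
    grand = all_values.mean()
    k = len(groups)
    n = all_values.size
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, n - k
    msw = ssw / df_w
    if msw == 0.0:
        F = 0.0 if ssb == 0.0 else float("inf")
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        F = (ssb / df_b) / msw
        p = float(sps.f.sf(F, df_b, df_w))
    tukey: dict = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            va, vb = data[ga], data[gb]
            diff = va.mean() - vb.mean()
            if msw == 0.0:
                padj = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / va.size + 1.0 / vb.size))
                q = abs(diff) / se
                padj = float(sps.studentized_range.sf(q, k, df_w))
            tukey[(ga, gb)] = (float(diff), padj)
    resid = np.concatenate([data[g] - data[g].mean() for g in groups])
    shapiro_p = levene_p = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            shapiro_p = float(sps.shapiro(resid).pvalue)
        except Exception:
            pass
        try:
            levene_p = float(sps.levene(*[data[g] for g in groups]).pvalue)
        except Exception:
            pass
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={g: float(v.mean()) for g, v in data.items()},
        tukey=tukey,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
    )


def mixed_slope(
    y, x, tree, ci_level: float = 0.95
) -> MixedSlopeResult:
    """Fixed slope of ``y`` on ``x`` with a random intercept per tree.

    Fitted by REML (statsmodels MixedLM) with a Wald CI on the slope.  With
    a single tree the model collapses to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    tree = np.asarray(tree)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x is constant")
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    if np.unique(tree).size < 2:
        slope, intercept, *_ = sps.linregress(x, y)
        resid = y - intercept - slope * x
        dof = max(y.size - 2, 1)
        s2 = float(resid @ resid) / dof
        se = np.sqrt(s2 / float(((x - x.mean()) ** 2).sum()))
        return MixedSlopeResult(
            slope=float(slope),
            intercept=float(intercept),
            slope_ci=(float(slope - z * se), float(slope + z * se)),
            tree_variance=0.0,
            residual_variance=s2,
        )
    from statsmodels.regression.mixed_linear_model import MixedLM

    exog = np.column_stack([np.ones_like(x), x])
    model = MixedLM(y, exog, groups=tree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs")
        slope = float(fit.fe_params[1])
        se = float(fit.bse_fe[1])
    if not np.isfinite(se):  # boundary fit (zero variance component)
        se = 0.0
    return MixedSlopeResult(
        slope=slope,
        intercept=float(fit.fe_params[0]),
        slope_ci=(slope - z * se, slope + z * se),
        tree_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
    )


def anova_to_frame(name: str, res: AnovaResult) -> pd.DataFrame:
    """Tidy report: the omnibus row followed by Tukey pairwise rows."""
    rows = [
        (
            name,
            "anova",
            "",
            "",
            res.F,
            f"{res.df_between},{res.df_within}",
            res.p,
        )
    ]
    for (ga, gb), (diff, padj) in sorted(res.tukey.items()):
        rows.append((name, "tukey", ga, gb, diff, "", padj))
    return pd.DataFrame(
        rows,
        columns=["test", "kind", "group_a", "group_b", "statistic", "df", "p"],
    )
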