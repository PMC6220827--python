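"""Group statistics: per-species summaries at three labeling stringencies,
one-way ANOVA per feature, and ANCOVA against valve length with per-group
regressions. Missing feature values are handled by complete-case analysis
per feature (group n may therefore differ among features)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .io import SPECIES

__all__ = [
    "group_membership",
    "summarize_groups",
    "AnovaResult",
    "feature_anova",
    "AncovaResult",
    "feature_ancova",
]

STRINGENCIES = ("unequivocal", "majority", "single_vote")


def group_membership(consensus: pd.DataFrame, stringency: str) -> dict[str, list[str]]:
    """Specimen ids per species under a labeling stringency.

    unequivocal: all nonempty votes for the species (percent_agree = 1);
    majority: species majority label (ties/ambiguous excluded);
    single_vote: at least one participant voted the species (specimens may
    appear in several groups).
    """
    if stringency not in STRINGENCIES:
        raise ValueError(f"unknown stringency {stringency!r}")
    cons = consensus.set_index("specimen_id") if "specimen_id" in consensus else consensus
    groups: dict[str, list[str]] = {}
    for sp in SPECIES:
        if stringency == "unequivocal":
            sel = (cons["majority_label"] == sp) & (cons["percent_agree"] >= 1.0)
        elif stringency == "majority":
            sel = cons["majority_label"] == sp
        else:
            sel = cons[f"n_{sp}"] >= 1
        groups[sp] = list(cons.index[sel])
    return groups


def summarize_groups(
    features: pd.DataFrame,
    consensus: pd.DataFrame,
    stringency: str = "majority",
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per species x feature: n, min, max, mean, SD (missing values ignored)."""
    feats = features.set_index("specimen_id")
    if feature_names is None:
        feature_names = [c for c in feats.columns if feats[c].dtype.kind in "fc"]
    groups = group_membership(consensus, stringency)
    rows = []
    for sp, ids in groups.items():
        ids = [i for i in ids if i in feats.index]
        sub = feats.loc[ids, feature_names]
        for name in feature_names:
            vals = sub[name].dropna()
            rows.append(
                {
                    "species": sp,
                    "feature": name,
                    "stringency": stringency,
                    "n": int(len(vals)),
                    "min": vals.min() if len(vals) else np.nan,
                    "max": vals.max() if len(vals) else np.nan,
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) else np.nan),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    feature: str
    F: float
    df1: int
    df2: int
    p: float
    coef_p: dict  # linear-model coefficient p-values (dummy-coded groups)


def feature_anova(values: pd.Series, groups: pd.Series, feature: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA on complete cases, via a linear model with
    dummy-coded groups (mirrors an `lm()` + `anova()` analysis)."""
    df = pd.DataFrame({"y": values, "g": groups}).dropna()
    level_counts = df["g"].value_counts()
    if len(level_counts) < 2:
        raise ValueError("need >= 2 groups")
    small = level_counts[level_counts < 2]
    if not small.empty:
        raise ValueError(f"group(s) with < 2 observations: {list(small.index)}")
    fit = smf.ols("y ~ C(g)", data=df).fit()
    table = anova_lm(fit, typ=1)
    F = float(table.loc["C(g)", "F"])
    ss_group = float(table.loc["C(g)", "sum_sq"])
    ss_scale = float((df["y"] - df["y"].mean()).pow(2).sum())
    if ss_group <= 1e-12 * max(ss_scale, 1.0):  # no between-group signal
        F = 0.0
    elif not np.isfinite(F):  # zero residual variance with real group signal
        F = np.inf
    return AnovaResult(
        feature=feature,
        F=F,
        df1=int(table.loc["C(g)", "df"]),
        df2=int(table.loc["Residual", "df"]),
        p=float(table.loc["C(g)", "PR(>F)"]),
        coef_p=dict(fit.pvalues),
    )


@dataclass
class AncovaResult:
    feature: str
    covariate: str
    F: float
    df1: int
    df2: int
    p: float
    coef_p: dict
    group_lines: pd.DataFrame  # per-group simple-regression intercept/slope


def feature_ancova(
    values: pd.Series,
    covariate: pd.Series,
    groups: pd.Series,
    feature: str = "",
    covariate_name: str = "length",
) -> AncovaResult:
    """Linear model with group, covariate, and group-by-covariate interaction,
    plus per-group simple least-squares lines."""
    df = pd.DataFrame({"y": values, "x": covariate, "g": groups}).dropna()
    n_groups = df["g"].nunique()
    if len(df) < n_groups * 2 + 2:
        raise ValueError("too few complete cases for ANCOVA")
    fit = smf.ols("y ~ C(g) * x", data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("singular design")
    lines = []
    for g, sub in df.groupby("g", observed=True):
        X = sm.add_constant(sub["x"])
        res = sm.OLS(sub["y"], X).fit()
        lines.append(
            {
                "group": g,
                "intercept": float(res.params["const"]),
                "slope": float(res.params["x"]),
                "n": len(sub),
            }
        )
    return AncovaResult(
        feature=feature,
        covariate=covariate_name,
        F=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        p=float(fit.f_pvalue),
        coef_p=dict(fit.pvalues),
        group_lines=pd.DataFrame(lines),
    )
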