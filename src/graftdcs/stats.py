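"""The cohort statistical battery.

Normality-gated two-sample comparisons (Student/Welch t or exact
Mann-Whitney U), a mixed repeated-measures ANOVA (between-subject GROUP,
within-subject TIME) with uncorrected per-group paired post hocs, OLS
regression with raw and standardized coefficients, and the
interhemispheric BDNF normalization.  No family-wise error correction is
applied anywhere; every result records its method, statistic, df, tails
and p so reports stay auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TestResult",
    "RegressionResult",
    "AnovaResult",
    "ks_normality",
    "two_sample_t",
    "mann_whitney_u",
    "auto_compare",
    "rm_anova_mixed",
    "ols_fit",
    "interhemispheric_ratio",
]

_EXACT_MW_LIMIT = 400  # exact U enumeration up to n_x * n_y of this size


@dataclass
class TestResult:
    statistic: float
    df: Optional[float]
    p: float
    tails: str
    method: str
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def ks_normality(x: Sequence[float]) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against N(mean(x), sd(x)).

    Because the reference normal uses parameters estimated from the same
    sample, the p value comes from the Lilliefors null distribution (the
    plain KS null would be far too conservative here).  Used as the gate
    that routes a comparison to the Mann-Whitney U test when normality
    is rejected.  A constant sample is degenerate and is flagged rather
    than tested.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("KS normality test needs at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult(
            statistic=float("nan"),
            df=None,
            p=float("nan"),
            tails="two",
            method="Kolmogorov-Smirnov (normality)",
            extra={"degenerate": True, "reason": "constant sample"},
        )
    if len(x) >= 4:
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
        method = "Kolmogorov-Smirnov (normality, Lilliefors null)"
    else:
        # Lilliefors tables need n >= 4; n = 3 falls back to the plain null
        stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
        method = "Kolmogorov-Smirnov (normality)"
    return TestResult(
        statistic=float(stat),
        df=None,
        p=float(p),
        tails="two",
        method=method,
    )


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "student",
    tails: str = "two",
) -> TestResult:
    """Independent-samples t test (pooled-variance Student or Welch).

    ``tails="upper"`` tests the directed hypothesis mean(x) > mean(y)
    (used for the BDNF contrast); the default is two-tailed.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if tails not in ("two", "upper"):
        raise ValueError("tails must be 'two' or 'upper'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    degenerate = x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean()
    alternative = "two-sided" if tails == "two" else "greater"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.ttest_ind(x, y, equal_var=(variant == "student"), alternative=alternative)
    extra = {"variant": variant}
    if degenerate:
        extra["degenerate"] = True
        extra["reason"] = "zero variance in both samples with equal means"
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        tails=tails,
        method=f"t test ({variant}, independent samples)",
        extra=extra,
    )


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U with exact enumeration for small samples.

    Exact null distribution when n_x * n_y <= 400 and there are no ties,
    otherwise the tie-corrected normal approximation (with continuity
    correction).  The Z statistic of the approximation is always
    reported alongside U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each sample needs at least 1 observation")
    nx, ny = len(x), len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < nx + ny
    exact = nx * ny <= _EXACT_MW_LIMIT and not ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
    u = float(res.statistic)
    mu = nx * ny / 2.0
    ranks = sps.rankdata(np.concatenate([x, y]))
    n = nx + ny
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma = np.sqrt(nx * ny / 12.0 * ((n + 1) - tie_term))
    z = 0.0 if sigma == 0 else (u - mu) / sigma
    return TestResult(
        statistic=u,
        df=None,
        p=float(res.pvalue),
        tails="two",
        method="Mann-Whitney U (exact)" if exact else "Mann-Whitney U (normal approximation)",
        extra={"z": float(z), "exact": bool(exact)},
    )


def auto_compare(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "student",
    tails: str = "two",
    alpha: float = 0.05,
) -> TestResult:
    """Normality-gated comparison: t test unless KS rejects for a sample."""
    normal = True
    for sample in (x, y):
        if len(sample) >= 3:
            ks = ks_normality(sample)
            if np.isfinite(ks.p) and ks.p < alpha:
                normal = False
    if normal:
        res = two_sample_t(x, y, variant=variant, tails=tails)
    else:
        res = mann_whitney_u(x, y)
    res.extra["normality_gate"] = "t" if normal else "mann-whitney"
    return res


@dataclass
class AnovaResult:
    time: TestResult
    group: TestResult
    interaction: TestResult
    gg_epsilon: Optional[float]
    posthoc: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "time": self.time.to_dict(),
            "group": self.group.to_dict(),
            "interaction": self.interaction.to_dict(),
            "gg_epsilon": self.gg_epsilon,
            "posthoc": self.posthoc.to_dict(orient="records"),
        }


def _effect_from_row(row: pd.Series, name: str) -> TestResult:
    f = float(row["F"])
    p = float(row["p_unc"] if "p_unc" in row.index else row["p-unc"])
    ss = float(row.get("SS", np.nan))
    if not np.isfinite(f) and (not np.isfinite(ss) or ss <= 1e-12):
        # a zero effect over a zero error term: report no effect, not NaN
        f, p = 0.0, 1.0
    return TestResult(
        statistic=f,
        df=float(row["DF1"]),
        p=p,
        tails="two",
        method=f"mixed RM-ANOVA ({name})",
        extra={"df_error": float(row["DF2"]), "SS": ss},
    )


def _mixed_anova_sums_of_squares(wide: pd.DataFrame, group_of: pd.Series) -> dict:
    """Split-plot ANOVA from first principles (balanced within-design).

    Used when the library implementation cannot handle the input
    (typically zero-variance degenerate data).  Zero effect over a zero
    error term reports F = 0, p = 1 rather than NaN.
    """
    y = wide.to_numpy(dtype=float)
    subjects = wide.index
    groups = group_of.reindex(subjects).astype(str)
    levels = sorted(groups.unique())
    k = y.shape[1]
    n_total = y.shape[0]
    gm = y.mean()
    subj_means = y.mean(axis=1)
    group_means = {g: subj_means[(groups == g).to_numpy()].mean() for g in levels}
    time_means = y.mean(axis=0)

    ss_group = k * sum(
        (groups == g).sum() * (group_means[g] - gm) ** 2 for g in levels
    )
    ss_subj = k * sum(
        ((subj_means[(groups == g).to_numpy()] - group_means[g]) ** 2).sum() for g in levels
    )
    ss_time = n_total * ((time_means - gm) ** 2).sum()
    cell = {g: y[(groups == g).to_numpy()].mean(axis=0) for g in levels}
    ss_inter = sum(
        (groups == g).sum() * ((cell[g] - group_means[g] - time_means + gm) ** 2).sum()
        for g in levels
    )
    ss_err = 0.0
    for g in levels:
        sel = (groups == g).to_numpy()
        resid = y[sel] - cell[g][None, :] - subj_means[sel][:, None] + group_means[g]
        ss_err += (resid**2).sum()

    n_groups = len(levels)
    df = {
        "group": (n_groups - 1, n_total - n_groups),
        "time": (k - 1, (n_total - n_groups) * (k - 1)),
        "interaction": ((n_groups - 1) * (k - 1), (n_total - n_groups) * (k - 1)),
    }
    ms_subj = ss_subj / max(df["group"][1], 1)
    ms_err = ss_err / max(df["time"][1], 1)

    def f_and_p(ss_effect, df1, df2, ms_denominator):
        if ss_effect <= 1e-12 or df1 == 0:
            return 0.0, 1.0
        if ms_denominator <= 0:
            return float("inf"), 0.0
        f = (ss_effect / df1) / ms_denominator
        return float(f), float(sps.f.sf(f, df1, df2))

    out = {}
    for name, ss_effect, denom in (
        ("group", ss_group, ms_subj),
        ("time", ss_time, ms_err),
        ("interaction", ss_inter, ms_err),
    ):
        df1, df2 = df[name]
        f, p = f_and_p(ss_effect, df1, df2, denom)
        out[name] = {"F": f, "p-unc": p, "SS": float(ss_effect), "DF1": df1, "DF2": df2}
    return out


def rm_anova_mixed(
    data: pd.DataFrame,
    dv: str = "net_turns_per_min",
    within: str = "timepoint",
    subject: str = "animal_id",
    between: str = "group",
    baseline_level: str = "baseline",
) -> AnovaResult:
    """Mixed-design repeated-measures ANOVA (TIME within, GROUP between).

    Univariate, sphericity assumed; the Greenhouse-Geisser epsilon is
    computed and reported but not applied.  Post hoc: per-group paired t
    tests of each later timepoint against baseline, uncorrected.
    Requires a complete design (every subject measured at every
    timepoint).
    """
    for col in (dv, within, subject, between):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from the dataset")
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete design: subjects {missing} lack timepoints")

    group_of = data.groupby(subject)[between].first()
    eps = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # correction=True also computes the GG epsilon; uncorrected
            # p values (p-unc) are what the pipeline reports
            aov = pg.mixed_anova(
                data=data, dv=dv, within=within, subject=subject, between=between,
                correction=True,
            )
        aov = aov.set_index("Source")
        group_row = aov.loc[between]
        time_row = aov.loc[within]
        inter_row = aov.loc["Interaction"]
        if "eps" in aov.columns and np.isfinite(time_row.get("eps", np.nan)):
            eps = float(time_row["eps"])
    except Exception:
        # zero-variance/degenerate inputs: fall back to first-principles SS
        table = _mixed_anova_sums_of_squares(wide, group_of)
        group_row = pd.Series(table["group"])
        time_row = pd.Series(table["time"])
        inter_row = pd.Series(table["interaction"])

    rows = []
    groups = data[between].unique()
    levels = [lv for lv in data[within].unique() if lv != baseline_level]
    for g in sorted(map(str, groups)):
        sub = data[data[between].astype(str) == g]
        base = sub[sub[within] == baseline_level].set_index(subject)[dv]
        for lv in levels:
            later = sub[sub[within] == lv].set_index(subject)[dv]
            later = later.reindex(base.index)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = sps.ttest_rel(later.to_numpy(), base.to_numpy())
            rows.append(
                {
                    "group": g,
                    "timepoint": lv,
                    "t": float(t.statistic),
                    "df": int(len(base) - 1),
                    "p": float(t.pvalue),
                    "method": "paired t vs baseline (uncorrected)",
                }
            )
    posthoc = pd.DataFrame(rows)
    return AnovaResult(
        time=_effect_from_row(time_row, "TIME"),
        group=_effect_from_row(group_row, "GROUP"),
        interaction=_effect_from_row(inter_row, "GROUP x TIME"),
        gg_epsilon=eps,
        posthoc=posthoc,
    )


@dataclass
class RegressionResult:
    params: dict
    params_standardized: dict
    tvalues: dict
    pvalues: dict
    bse: dict
    fvalue: float
    f_pvalue: float
    rsquared: float
    n: int
    df_resid: float

    def to_dict(self) -> dict:
        return asdict(self)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    bad = []
    arr = X.to_numpy(dtype=float)
    for j, col in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        if others.shape[1] == 0:
            continue
        beta, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
        resid = arr[:, j] - others @ beta
        denom = np.sum((arr[:, j] - arr[:, j].mean()) ** 2)
        if denom == 0 or 1 - np.sum(resid**2) / max(denom, 1e-300) > 1 - 1e-10:
            bad.append(str(col))
    return bad


def ols_fit(y: Sequence[float], predictors: pd.DataFrame) -> RegressionResult:
    """OLS with intercept; raw and standardized coefficients.

    Standardized coefficients are b_j * sd(x_j) / sd(y).  Categorical
    group membership must already be numerically coded by the caller
    (the pipeline codes sham=0, anodal=1, cathodal=2 and records the
    coding in its report).  A rank-deficient design raises an error
    naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    if len(y) != len(X):
        raise ValueError("y and predictors must have the same length")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1 observations")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        bad = _collinear_columns(Xc)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-y edge cases
        fit = sm.OLS(y, Xc).fit()
    sd_y = y.std(ddof=1)
    std_params = {}
    for col in X.columns:
        sd_x = X[col].std(ddof=1)
        std_params[str(col)] = (
            float(fit.params[col] * sd_x / sd_y) if sd_y > 0 and sd_x > 0 else 0.0
        )
    fvalue = float(fit.fvalue) if np.isfinite(fit.fvalue) else 0.0
    return RegressionResult(
        params={str(k): float(v) for k, v in fit.params.items()},
        params_standardized=std_params,
        tvalues={str(k): float(v) for k, v in fit.tvalues.items()},
        pvalues={str(k): float(v) for k, v in fit.pvalues.items()},
        bse={str(k): float(v) for k, v in fit.bse.items()},
        fvalue=fvalue,
        f_pvalue=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0,
        rsquared=float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0,
        n=int(fit.nobs),
        df_resid=float(fit.df_resid),
    )


def interhemispheric_ratio(stim_value: float, contra_value: float) -> float:
    """Stimulated-hemisphere analyte content as % of the contralateral side."""
    if contra_value <= 0:
        raise ValueError("contralateral value must be > 0")
    return 100.0 * stim_value / contra_value
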