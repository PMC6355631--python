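"""Group-level statistics for the permeability cohort.

Covers the study-level analyses downstream of the per-subject kinetic fits:
Bland-Altman agreement between the manual-ROI and segmentation analysis
paths, the two-way mixed single-measure consistency intraclass correlation
ICC(3,1), ANCOVA comparison of patient and control influx constants with
age as covariate, paired nonparametric/parametric comparisons (grey vs
white matter), and the multivariate regression of K_i on CBV, CBF and
tissue type.

No multiple-testing correction is applied; p-values are reported unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "BlandAltmanResult",
    "IccResult",
    "AncovaResult",
    "bland_altman",
    "icc_single_measure_consistency",
    "group_compare_ancova",
    "paired_compare",
    "regress_ki",
]

COHORT_COLUMNS = ["subject_id", "group", "age", "region", "method", "ki", "cbv", "cbf"]


@dataclass
class BlandAltmanResult:
    """Bland-Altman limits of agreement between two measurement methods.

    Differences are method1 - method2.  The limits of agreement (LoA) use
    the conventional 1.96 multiplier; the 95% confidence interval of each
    limit uses the t distribution with n-1 degrees of freedom and standard
    error sqrt(3 s^2 / n).
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_upper: float
    loa_lower: float
    loa_width: float
    ci_upper_loa: tuple[float, float]
    ci_lower_loa: tuple[float, float]

    def summary(self) -> str:
        return "\n".join(
            [
                "Bland-Altman agreement",
                "-" * 52,
                f"n                        {self.n:10d}",
                f"Mean difference          {self.mean_diff:10.5f}",
                f"SD of difference         {self.sd_diff:10.5f}",
                f"Upper 95% LoA            {self.loa_upper:10.5f}  "
                f"(95% CI {self.ci_upper_loa[0]:.5f} to {self.ci_upper_loa[1]:.5f})",
                f"Lower 95% LoA            {self.loa_lower:10.5f}  "
                f"(95% CI {self.ci_lower_loa[0]:.5f} to {self.ci_lower_loa[1]:.5f})",
                f"Width between LoA        {self.loa_width:10.5f}",
            ]
        )


def bland_altman(
    values_method1: np.ndarray,
    values_method2: np.ndarray | None = None,
) -> BlandAltmanResult:
    """Bland-Altman analysis of paired measurements.

    Accepts either two equal-length arrays or a single (n, 2) array of
    pairs.  Requires n >= 3 complete pairs.  With zero variance the limits
    collapse onto the mean difference and the CIs are degenerate (warned).
    """
    if values_method2 is None:
        pairs = np.asarray(values_method1, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of pairs")
        a, b = pairs[:, 0], pairs[:, 1]
    else:
        a = np.asarray(values_method1, dtype=float)
        b = np.asarray(values_method2, dtype=float)
        if a.shape != b.shape:
            raise ValueError("method value arrays must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    d = (a - b)[keep]
    n = d.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0:
        warnings.warn("zero variance of differences; limits of agreement collapse")
    half = 1.96 * sd_diff
    loa_upper = mean_diff + half
    loa_lower = mean_diff - half
    se_loa = np.sqrt(3.0 * sd_diff**2 / n)
    t_crit = float(stats.t.ppf(0.975, n - 1))
    return BlandAltmanResult(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_upper=loa_upper,
        loa_lower=loa_lower,
        loa_width=2 * 1.96 * sd_diff,
        ci_upper_loa=(loa_upper - t_crit * se_loa, loa_upper + t_crit * se_loa),
        ci_lower_loa=(loa_lower - t_crit * se_loa, loa_lower + t_crit * se_loa),
    )


@dataclass
class IccResult:
    """Two-way mixed, single-measure, consistency ICC — ICC(3,1)."""

    icc: float
    ci: tuple[float, float]
    msr: float
    mse: float
    k: int
    n: int

    def summary(self) -> str:
        return (
            f"ICC(3,1) single-measure consistency: {self.icc:.3f} "
            f"(95% CI {self.ci[0]:.3f} to {self.ci[1]:.3f}); "
            f"n={self.n} subjects, k={self.k} methods"
        )


def icc_single_measure_consistency(matrix: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(3,1) from an n-subjects x k-methods matrix with no missing cells.

    From the two-way ANOVA decomposition with subjects as rows and methods
    (raters) as fixed columns,

        ICC(3,1) = (MSR - MSE) / (MSR + (k - 1) MSE)

    where MSR is the between-subject and MSE the residual mean square.  The
    confidence interval follows the standard F-distribution construction
    for consistency ICCs (McGraw & Wong convention):

        F = MSR / MSE,  FL = F / F_{1-a/2; n-1, (n-1)(k-1)},
        FU = F * F_{1-a/2; (n-1)(k-1), n-1},
        CI = ((FL-1)/(FL+k-1), (FU-1)/(FU+k-1)).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an n x k matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need n >= 3 subjects and k >= 2 methods")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not allowed (no imputation)")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    # residual sum of squares computed from the interaction terms directly
    # (stable; the subtraction form SS_tot - SS_rows - SS_cols cancels badly
    # when the residual is near zero)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if mse == 0 and msr == 0:
        raise ValueError("degenerate matrix: no variance at all")
    if mse == 0:
        icc = 1.0
        ci = (1.0, 1.0)
        return IccResult(icc=icc, ci=ci, msr=msr, mse=mse, k=k, n=n)

    icc = (msr - mse) / (msr + (k - 1) * mse)
    f_obs = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return IccResult(icc=float(icc), ci=(float(ci[0]), float(ci[1])), msr=msr, mse=mse, k=k, n=n)


@dataclass
class AncovaResult:
    """Group comparison adjusted for a scalar covariate (age)."""

    p_group: float
    p_covariate: float
    partial_eta_sq: float
    emm: dict[str, float]
    n_per_group: dict[str, int]

    def summary(self) -> str:
        emm = ", ".join(f"{g}: {v:.4f}" for g, v in self.emm.items())
        return (
            f"ANCOVA group effect: p={self.p_group:.4f}, partial eta^2="
            f"{self.partial_eta_sq:.3f}; age effect p={self.p_covariate:.4f}; "
            f"estimated marginal means [{emm}]"
        )


def group_compare_ancova(
    table: pd.DataFrame,
    outcome: str = "ki",
    factor: str = "group",
    covariate: str = "age",
) -> AncovaResult:
    """ANCOVA: ``outcome ~ factor + covariate`` with a two-level group factor.

    Returns the group-effect p-value, its partial eta squared
    SS_group / (SS_group + SS_error), the covariate p-value, and the
    estimated marginal means (group predictions at the grand-mean
    covariate).  A zero-variance covariate degrades gracefully to a one-way
    ANOVA on the factor.
    """
    df = table[[outcome, factor, covariate]].dropna().copy()
    groups = sorted(df[factor].unique())
    if len(groups) < 2:
        raise ValueError("both groups must be represented")
    cov_varies = df[covariate].nunique() > 1
    formula = f"{outcome} ~ C({factor})" + (f" + {covariate}" if cov_varies else "")
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    ss_group = float(anova.loc[f"C({factor})", "sum_sq"])
    ss_err = float(anova.loc["Residual", "sum_sq"])
    p_group = float(anova.loc[f"C({factor})", "PR(>F)"])
    p_cov = float(anova.loc[covariate, "PR(>F)"]) if cov_varies else np.nan

    grand_age = df[covariate].mean()
    pred = pd.DataFrame({factor: groups, covariate: grand_age})
    emm = dict(zip(groups, model.predict(pred)))
    return AncovaResult(
        p_group=p_group,
        p_covariate=p_cov,
        partial_eta_sq=ss_group / (ss_group + ss_err),
        emm={g: float(v) for g, v in emm.items()},
        n_per_group=df[factor].value_counts().to_dict(),
    )


def paired_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    test: str = "wilcoxon",
) -> tuple[float, float]:
    """Two-tailed paired comparison: Wilcoxon signed-rank or paired t test.

    The Wilcoxon test uses the exact null distribution for n <= 25 (no
    ties/zeros) and the tie-corrected normal approximation otherwise.
    All-zero differences leave the signed-rank statistic undefined and
    raise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if test == "wilcoxon":
        if a.size < 5:
            raise ValueError("need n >= 5 for the Wilcoxon test")
        if np.all(d == 0):
            raise ValueError("all differences are zero; Wilcoxon statistic undefined")
        method = "exact" if (a.size <= 25 and not np.any(d == 0) and
                             np.unique(np.abs(d)).size == a.size) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                             correction=(method == "approx"))
        return float(res.statistic), float(res.pvalue)
    if test == "paired_t":
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def regress_ki(table: pd.DataFrame, predictors: tuple[str, ...] = ("cbv", "cbf", "tissue")):
    """Multivariate OLS of K_i on CBV, CBF and tissue type.

    ``tissue`` may be a 0/1 indicator or a two-level label column.  Returns
    the fitted statsmodels results object (coefficient table, r^2, per-term
    p-values via ``.params``, ``.rsquared``, ``.pvalues``).  A numerically
    collinear design raises rather than silently dropping a term.
    """
    df = table.copy()
    if df["tissue"].dtype == object:
        levels = sorted(df["tissue"].unique())
        if len(levels) > 2:
            raise ValueError("tissue must have at most two levels")
        df["tissue"] = (df["tissue"] == levels[-1]).astype(float)
    if len(df) < len(predictors) + 3:
        raise ValueError("need at least 3 more rows than predictors")
    x = sm.add_constant(df[list(predictors)].astype(float))
    rank = np.linalg.matrix_rank(x.values)
    if rank < x.shape[1]:
        raise ValueError("collinear design: a predictor is a linear combination of others")
    model = sm.OLS(df["ki"].astype(float), x).fit()
    if np.linalg.cond(x.values) > 1e10:
        warnings.warn("ill-conditioned design matrix; coefficients may be unstable")
    return model
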