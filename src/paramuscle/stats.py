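"""Cohort statistics: gated group comparisons, ICC reliability, OLS with VIF.

The battery reproduces the statistical workflow of a two-arm surgical
cohort study:

* categorical baseline variables compared by Pearson χ² (no continuity
  correction by default), switching to Fisher's exact test whenever any
  expected cell count falls below 5;
* continuous variables gated by Shapiro–Wilk normality into a pooled
  two-sample Student t (normal) or a Mann–Whitney U reported as a
  tie-corrected normal-approximation Z (non-normal);
* inter-rater reliability as ICC(A,k): two-way model, absolute agreement,
  mean of k = 2 raters, with McGraw–Wong confidence limits and the
  F = MSR/MSE test against a true value of 0;
* a multivariable OLS of Average-ΔRCSA on the clinical covariates with
  standardized coefficients and tolerance/VIF collinearity diagnostics;
* the intraoperative blood-loss estimator (suction net of irrigation plus
  0.56 mL per gram of gauze weight gain).

Significance is declared at the study's α = 0.01 (two-sided throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import CollinearityError

ALPHA = 0.01
#: blood absorbed per gram of gauze weight gain (mL/g)
BLOOD_ML_PER_GRAM = 0.56

ICC_BANDS = (
    (0.90, "excellent"),
    (0.80, "good"),
    (0.70, "acceptable"),
)


@dataclass
class StatResult:
    """One test or one regression coefficient, reporting-table style."""

    name: str
    statistic: float
    statistic_name: str
    p_value: float
    df: float | tuple | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    effect: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.ci_low is not None and self.ci_high is not None and self.ci_low > self.ci_high:
            raise ValueError(f"ci_low {self.ci_low} > ci_high {self.ci_high}")

    @property
    def significant(self) -> bool:
        return significance_flag(self.p_value)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "statistic_name": self.statistic_name,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "effect": self.effect,
            "diagnostics": self.diagnostics,
            "method": self.method,
            "significant": self.significant,
        }


def significance_flag(p: float) -> bool:
    """True iff p < 0.01, the study-wide two-sided significance level."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    return p < ALPHA


# ---------------------------------------------------------------------------
# categorical tests


def _as_count_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.float64)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError(f"contingency table must be at least 2x2, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("contingency table must hold non-negative integer counts")
    return t


def expected_counts(table) -> np.ndarray:
    """Expected cell counts from the row/column margins."""
    t = _as_count_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin; expected counts undefined")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def pearson_chi2(table, continuity_correction: bool = False, name: str = "chi2") -> StatResult:
    """Pearson χ² test of independence with Cramér's V effect size."""
    t = _as_count_table(table)
    expected = expected_counts(t)  # raises on zero margins
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=continuity_correction)
    n = t.sum()
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1)))) if chi2 > 0 else 0.0
    return StatResult(
        name=name,
        statistic=float(chi2),
        statistic_name="chi2",
        df=float(dof),
        p_value=float(p),
        effect={"cramers_v": v},
        diagnostics={"min_expected": float(expected.min())},
        method="pearson_chi2" + ("_yates" if continuity_correction else ""),
    )


def fisher_exact(table, name: str = "fisher") -> StatResult:
    """Fisher's exact test on a 2x2 table (two-sided, probability method)."""
    t = _as_count_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"Fisher's exact test implemented for 2x2 tables only, got {t.shape}")
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return StatResult(
        name=name,
        statistic=float(odds),
        statistic_name="odds_ratio",
        p_value=float(p),
        method="fisher_exact",
    )


def test_selector_categorical(table) -> str:
    """'fisher' iff any expected cell count < 5, else 'chi2'."""
    return "fisher" if expected_counts(table).min() < 5 else "chi2"


def compare_categorical(table, name: str = "categorical", continuity_correction: bool = False) -> StatResult:
    """Gated categorical comparison: χ² or Fisher per the expected-count rule."""
    if test_selector_categorical(table) == "fisher":
        t = _as_count_table(table)
        if t.shape == (2, 2):
            return fisher_exact(table, name=name)
    return pearson_chi2(table, continuity_correction=continuity_correction, name=name)


# ---------------------------------------------------------------------------
# continuous tests


def shapiro_wilk_gate(sample_a, sample_b, alpha: float = 0.05) -> str:
    """'t_test' iff both samples pass Shapiro–Wilk normality at ``alpha``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for s in (a, b):
        if s.size < 3:
            raise ValueError(f"Shapiro–Wilk requires n >= 3, got n={s.size}")
    pa = sps.shapiro(a).pvalue
    pb = sps.shapiro(b).pvalue
    return "t_test" if (pa > alpha and pb > alpha) else "mann_whitney"


def two_sample_t(
    mean_a=None, sd_a=None, n_a=None, mean_b=None, sd_b=None, n_b=None,
    *, sample_a=None, sample_b=None, name: str = "t_test",
) -> StatResult:
    """Pooled-variance (Student) two-sample t, from summaries or raw samples.

    Summaries are the printed ``mean ± SD (n)`` form of clinical tables;
    when raw samples are given the summaries are computed with the n−1 SD.
    """
    if sample_a is not None:
        a = np.asarray(sample_a, float)
        b = np.asarray(sample_b, float)
        mean_a, sd_a, n_a = a.mean(), a.std(ddof=1), a.size
        mean_b, sd_b, n_b = b.mean(), b.std(ddof=1), b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance; t undefined")
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    t = (mean_a - mean_b) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(1 - ALPHA / 2, df)
    diff = mean_a - mean_b
    return StatResult(
        name=name,
        statistic=float(t),
        statistic_name="t",
        df=float(df),
        p_value=float(p),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        effect={"mean_difference": float(diff)},
        method="student_t_pooled",
    )


def mann_whitney_u(sample_a, sample_b, name: str = "mann_whitney") -> StatResult:
    """Mann–Whitney U with the tie-corrected normal-approximation Z.

    Z = (U_a − n_a·n_b/2) / sqrt(var), var tie-corrected, no continuity
    correction: clinical tables print Z rather than U.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical across both samples; Z undefined")
    ranks = sps.rankdata(pooled)
    n_a, n_b = a.size, b.size
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    z = (u_a - n_a * n_b / 2.0) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return StatResult(
        name=name,
        statistic=float(z),
        statistic_name="Z",
        p_value=float(p),
        effect={"U": float(u_a)},
        method="mann_whitney_normal_approx",
    )


def compare_continuous(sample_a, sample_b, name: str = "continuous", normality_alpha: float = 0.05) -> StatResult:
    """Normality-gated two-group comparison (Student t or Mann–Whitney Z)."""
    if shapiro_wilk_gate(sample_a, sample_b, alpha=normality_alpha) == "t_test":
        return two_sample_t(sample_a=sample_a, sample_b=sample_b, name=name)
    return mann_whitney_u(sample_a, sample_b, name=name)


# ---------------------------------------------------------------------------
# inter-rater reliability


@dataclass
class ICCResult:
    """ICC(A,k) summary: estimate, 95% CI, F test vs 0, interpretation band."""

    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    f_df: tuple
    f_p: float
    band: str
    anova: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.icc > 1.0 + 1e-12:
            raise ValueError(f"ICC cannot exceed 1, got {self.icc}")


def icc_band(icc: float) -> str:
    for threshold, label in ICC_BANDS:
        if icc > threshold:
            return label
    return "poor"


def icc_a_k(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC for absolute agreement of the mean of k=2 raters (two-way model).

    From the two-way ANOVA of an n x 2 ratings grid (rows = subjects,
    columns = raters):

        ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE) / n)

    with the McGraw–Wong confidence limits (single-measure limits with a
    Satterthwaite denominator df, stepped up to the average measure) and
    the F = MSR/MSE test against a true ICC of 0.
    """
    x = np.asarray(ratings, dtype=float)
    if isinstance(ratings, pd.DataFrame):
        x = ratings.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"ratings must be an n x 2 grid, got shape {x.shape}")
    n, k = x.shape
    if n < 5:
        raise ValueError(f"at least 5 subjects required, got {n}")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite cells; no imputation is performed")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (msc - mse) / n
    icc_k = 1.0 if denom == 0 else (msr - mse) / denom
    # single-measure companion used for the CI step-up
    denom1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_1 = (msr - mse) / denom1 if denom1 != 0 else 1.0

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        f_value, f_p = np.inf, 0.0
        low_k = high_k = icc_k
    else:
        f_value = msr / mse
        f_p = float(sps.f.sf(f_value, df1, df2))
        # Satterthwaite df for the ICC(A,1) interval (McGraw & Wong 1996)
        a = (k * icc_1) / (n * (1.0 - icc_1)) if icc_1 < 1 else np.inf
        b = 1.0 + (k * icc_1 * (n - 1)) / (n * (1.0 - icc_1)) if icc_1 < 1 else np.inf
        if np.isfinite(a) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            fu = sps.f.ppf(1 - alpha / 2, n - 1, v)
            fl = sps.f.ppf(1 - alpha / 2, v, n - 1)
            low_1 = n * (msr - fu * mse) / (fu * (k * msc + (k * n - k - n) * mse) + n * msr)
            high_1 = n * (fl * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fl * msr)
            low_k = k * low_1 / (1.0 + (k - 1) * low_1)
            high_k = k * high_1 / (1.0 + (k - 1) * high_1)
        else:
            low_k = high_k = icc_k
    return ICCResult(
        icc=float(icc_k),
        ci_low=float(min(low_k, high_k)),
        ci_high=float(max(low_k, high_k)),
        f_value=float(f_value),
        f_df=(df1, df2),
        f_p=float(f_p),
        band=icc_band(float(icc_k)),
        anova={"msr": float(msr), "msc": float(msc), "mse": float(mse)},
    )


# ---------------------------------------------------------------------------
# multivariable regression


@dataclass
class RegressionResult:
    """OLS fit summary: per-covariate rows plus residual diagnostics."""

    coefficients: list  # StatResult per covariate (and intercept)
    r_squared: float
    adj_r_squared: float
    n: int
    residual_diagnostics: pd.DataFrame = field(repr=False, default=None)

    def row(self, name: str) -> StatResult:
        for r in self.coefficients:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "coefficients": [r.to_dict() for r in self.coefficients],
        }


def _aux_r_squared(X: pd.DataFrame, col: str) -> float:
    """R² of covariate ``col`` regressed (with intercept) on the others."""
    others = X.drop(columns=[col])
    model = sm.OLS(X[col].to_numpy(float), sm.add_constant(others.to_numpy(float))).fit()
    return float(model.rsquared)


def multivariable_ols(y, X: pd.DataFrame, alpha: float = 0.05) -> RegressionResult:
    """Multivariable OLS with standardized betas and tolerance/VIF.

    Per covariate j: unstandardized beta, standardized beta
    b_j·sd(x_j)/sd(y) with n−1 sample SDs, t, two-sided p, the (1−alpha)
    CI, tolerance = 1 − R²_j and VIF = 1/tolerance where R²_j comes from
    regressing covariate j on all the others.  Exact collinearity raises
    :class:`CollinearityError` naming the dependent columns.
    """
    X = pd.DataFrame(X).astype(float)
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} covariates plus intercept")
    if X.isna().any().any() or np.any(~np.isfinite(yv)):
        raise ValueError("missing values in the design; complete cases required")

    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        culprits = [c for c in X.columns if _aux_r_squared(X, c) > 1 - 1e-10]
        raise CollinearityError(culprits or list(X.columns))

    fit = sm.OLS(yv, design).fit()
    sd_y = yv.std(ddof=1)
    conf = fit.conf_int(alpha=alpha)
    rows = []
    for term in design.columns:
        entry = StatResult(
            name=str(term),
            statistic=float(fit.tvalues[term]),
            statistic_name="t",
            df=float(fit.df_resid),
            p_value=float(fit.pvalues[term]),
            ci_low=float(conf.loc[term, 0]),
            ci_high=float(conf.loc[term, 1]),
            effect={"beta": float(fit.params[term])},
            method="ols",
        )
        if term != "const":
            tol = 1.0 - _aux_r_squared(X, term) if p > 1 else 1.0
            entry.effect["standardized_beta"] = float(
                fit.params[term] * X[term].std(ddof=1) / sd_y
            )
            entry.diagnostics = {"tolerance": tol, "vif": 1.0 / tol if tol > 0 else np.inf}
        rows.append(entry)

    resid = fit.resid
    std_resid = resid / np.sqrt(fit.mse_resid)
    order = np.argsort(std_resid.to_numpy() if hasattr(std_resid, "to_numpy") else std_resid)
    std_resid = np.asarray(std_resid)
    ecdf = (np.arange(1, n + 1) - 0.5) / n
    diag = pd.DataFrame(
        {
            "fitted": np.asarray(fit.fittedvalues),
            "std_residual": std_resid,
        }
    )
    diag["pp_observed"] = np.nan
    diag.loc[order, "pp_observed"] = ecdf
    diag["pp_expected"] = sps.norm.cdf(std_resid)
    return RegressionResult(
        coefficients=rows,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=n,
        residual_diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# blood loss


def estimate_blood_loss(suction_total: float, irrigation: float, gauze_weight_gain: float) -> float:
    """Intraoperative blood loss in mL.

    Net suction (total output minus irrigation fluid) plus gravimetric
    gauze estimate at 0.56 mL of blood per gram of weight gain.
    """
    if min(suction_total, irrigation, gauze_weight_gain) < 0:
        raise ValueError("all inputs must be non-negative")
    if irrigation > suction_total:
        raise ValueError(
            f"irrigation ({irrigation} mL) exceeds total suction ({suction_total} mL)"
        )
    return (suction_total - irrigation) + BLOOD_ML_PER_GRAM * gauze_weight_gain
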