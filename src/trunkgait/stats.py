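"""Cohort-level statistical models for gait-quality outcomes.

Implements the analysis layer applied to each of the twelve outcomes:

* continuous-age ordinary least squares with gender and BMI as covariates,
  where a quadratic age term is retained only when a nested F-test shows a
  significant improvement in fit;
* age-group ANCOVA with the omega-squared effect size and a stratified
  bootstrap confidence interval;
* Bonferroni-corrected covariate-adjusted pairwise group contrasts;
* incremental-variance (delta R^2) blocks for physical activity (MET) and
  hip strength (MS_average, MS_diff) with likelihood-ratio tests;
* muscle-group-specific association models.

Missing outcomes are handled by complete-case analysis per outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from trunkgait.errors import ModelError

logger = logging.getLogger(__name__)

ALPHA = 0.05


def age_decade(age: np.ndarray | pd.Series) -> pd.Series:
    """Decade label for each age (20-29 ... 70-79)."""
    lo = (np.asarray(age, dtype=float) // 10).astype(int) * 10
    return pd.Series([f"{a}-{a + 9}" for a in lo], index=getattr(age, "index", None))


def _gender_indicator(g: pd.Series) -> np.ndarray:
    """Binary male indicator from F/M strings or numeric coding."""
    if g.dtype == object:
        return (g.astype(str).str.upper() == "M").to_numpy(dtype=float)
    return g.to_numpy(dtype=float)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ModelError(f"rank-deficient design matrix (columns: {names})")


@dataclass
class _OLSFit:
    """Minimal OLS fit on an explicit design matrix (first column constant)."""

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    ssr: float          # residual sum of squares
    sst: float          # total sum of squares (about the mean)
    df_resid: int
    n: int

    @property
    def r2(self) -> float:
        return 1.0 - self.ssr / self.sst

    @property
    def r2_adj(self) -> float:
        return 1.0 - (self.ssr / self.df_resid) / (self.sst / (self.n - 1))

    @property
    def llf(self) -> float:
        # Gaussian log-likelihood at the MLE variance
        s2 = self.ssr / self.n
        return -0.5 * self.n * (np.log(2 * np.pi * s2) + 1.0)

    def t_pvalues(self) -> np.ndarray:
        t = self.beta / self.se
        return 2.0 * sps.t.sf(np.abs(t), self.df_resid)


def _ols(y: np.ndarray, X: np.ndarray) -> _OLSFit:
    n, p = X.shape
    if n <= p:
        raise ModelError(f"too few observations ({n}) for {p} parameters")
    res = sm.OLS(y, X).fit()
    return _OLSFit(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        cov=np.asarray(res.cov_params()),
        ssr=float(res.ssr),
        sst=float(res.centered_tss),
        df_resid=int(res.df_resid),
        n=n,
    )


def _nested_f(reduced: _OLSFit, full: _OLSFit) -> tuple[float, float]:
    """F statistic and p value for the parameters added in ``full``."""
    df_num = reduced.df_resid - full.df_resid
    if df_num <= 0:
        raise ModelError("models are not nested")
    f = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
    p = float(sps.f.sf(f, df_num, full.df_resid))
    return float(f), p


@dataclass
class RegressionResult:
    """Continuous-age model fit for one outcome."""

    outcome: str
    n: int
    intercept: float
    intercept_se: float
    slope_age: float
    slope_age_se: float
    quad_age: float | None
    quad_age_se: float | None
    rmse: float
    r2_adj: float
    f_stat: float
    p_age: float


def _complete_cases(cohort: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return cohort.dropna(subset=cols)


def fit_age_model(
    cohort: pd.DataFrame,
    outcome: str,
    alpha: float = ALPHA,
    force_quadratic: bool | None = None,
    min_n: int = 20,
) -> RegressionResult:
    """OLS of an outcome on age with gender and BMI as covariates.

    A quadratic age term is retained only when the nested F-test comparing
    the linear and quadratic models is significant at ``alpha``
    (``force_quadratic`` overrides the test in either direction).  The
    reported R^2 is adjusted (it can be negative for uninformative models);
    RMSE is the residual standard error; the F statistic and p value refer
    to the age terms as a block.
    """
    df = _complete_cases(cohort, ["age", "gender", "bmi", outcome])
    if len(df) < min_n:
        raise ModelError(f"{outcome}: only {len(df)} complete rows (< {min_n})")
    y = df[outcome].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    male = _gender_indicator(df["gender"])
    bmi = df["bmi"].to_numpy(dtype=float)
    n = len(y)
    const = np.ones(n)

    X_cov = np.column_stack([const, male, bmi])
    X_lin = np.column_stack([const, age, male, bmi])
    X_quad = np.column_stack([const, age, age**2, male, bmi])
    _check_rank(X_lin, ["const", "age", "gender", "bmi"])

    fit_cov = _ols(y, X_cov)
    fit_lin = _ols(y, X_lin)
    fit_quad = _ols(y, X_quad)

    if force_quadratic is None:
        if fit_lin.ssr <= 1e-12 * max(fit_lin.sst, 1.0):
            use_quad = False  # numerically perfect linear fit: nothing to improve
        else:
            _, p_improve = _nested_f(fit_lin, fit_quad)
            use_quad = p_improve < alpha
    else:
        use_quad = force_quadratic

    fit = fit_quad if use_quad else fit_lin
    f_age, p_age = _nested_f(fit_cov, fit)
    return RegressionResult(
        outcome=outcome,
        n=n,
        intercept=float(fit.beta[0]),
        intercept_se=float(fit.se[0]),
        slope_age=float(fit.beta[1]),
        slope_age_se=float(fit.se[1]),
        quad_age=float(fit.beta[2]) if use_quad else None,
        quad_age_se=float(fit.se[2]) if use_quad else None,
        rmse=float(np.sqrt(fit.ssr / fit.df_resid)),
        r2_adj=float(fit.r2_adj),
        f_stat=f_age,
        p_age=p_age,
    )


@dataclass
class AncovaResult:
    outcome: str
    n: int
    f_group: float
    p_group: float
    omega2: float
    omega2_ci: tuple[float, float] | None
    covariates: tuple[str, ...]
    group_means_adj: dict = field(default_factory=dict)


def _ancova_design(df: pd.DataFrame, outcome: str, covariates: tuple[str, ...]):
    groups = age_decade(df["age"])
    levels = sorted(groups.unique())
    y = df[outcome].to_numpy(dtype=float)
    n = len(y)
    dummies = np.column_stack([(groups == lv).to_numpy(dtype=float) for lv in levels[1:]])
    cov_cols = []
    for c in covariates:
        cov_cols.append(_gender_indicator(df[c]) if c == "gender" else df[c].to_numpy(dtype=float))
    X_full = np.column_stack([np.ones(n), dummies] + cov_cols)
    X_red = np.column_stack([np.ones(n)] + cov_cols) if cov_cols else np.ones((n, 1))
    return y, X_full, X_red, levels


def _omega2(y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray, df_group: int) -> tuple[float, float, float]:
    fit_full = _ols(y, X_full)
    fit_red = _ols(y, X_red)
    ss_group = fit_red.ssr - fit_full.ssr
    ms_error = fit_full.ssr / fit_full.df_resid
    omega2 = (ss_group - df_group * ms_error) / (fit_full.sst + ms_error)
    f = (ss_group / df_group) / ms_error
    p = float(sps.f.sf(f, df_group, fit_full.df_resid))
    return float(omega2), float(f), p


def ancova_group(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("gender", "bmi"),
    bootstrap_B: int = 2000,
    seed: int | None = None,
    ci: bool = True,
) -> AncovaResult:
    """Age-group ANCOVA with omega-squared and a stratified bootstrap CI.

    The age-decade factor is tested against the covariate-only model
    (partial sum of squares); omega^2 = (SS_group - df_group * MS_error) /
    (SS_total + MS_error), which can be slightly negative near the null.
    The 95 % CI resamples participants within their age-group strata
    (percentile interval over ``bootstrap_B`` replicates).
    """
    needed = ["age", outcome] + [c for c in covariates]
    df = _complete_cases(cohort, needed)
    groups = age_decade(df["age"])
    counts = groups.value_counts()
    if len(counts) < 2 or counts.min() < 3:
        raise ModelError(f"{outcome}: need >= 2 age groups with n >= 3 each")
    if df[outcome].std() == 0:
        raise ModelError(f"{outcome}: zero variance")

    y, X_full, X_red, levels = _ancova_design(df, outcome, covariates)
    df_group = len(levels) - 1
    omega2, f, p = _omega2(y, X_full, X_red, df_group)

    ci_bounds = None
    if ci and bootstrap_B > 0:
        rng = np.random.default_rng(seed)
        idx_by_group = [np.flatnonzero((groups == lv).to_numpy()) for lv in levels]
        boot = np.empty(bootstrap_B)
        for b in range(bootstrap_B):
            take = np.concatenate([rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_group])
            try:
                boot[b] = _omega2(y[take], X_full[take], X_red[take], df_group)[0]
            except ModelError:
                boot[b] = np.nan
        boot = boot[np.isfinite(boot)]
        ci_bounds = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    return AncovaResult(
        outcome=outcome,
        n=len(df),
        f_group=f,
        p_group=p,
        omega2=omega2,
        omega2_ci=ci_bounds,
        covariates=tuple(covariates),
    )


@dataclass
class PosthocTable:
    outcome: str
    contrasts: pd.DataFrame  # columns: group_a, group_b, estimate, p_raw, p_bonferroni


def posthoc_pairwise(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("gender", "bmi"),
) -> PosthocTable:
    """Covariate-adjusted pairwise age-group contrasts, Bonferroni corrected.

    Contrasts are differences of adjusted group means from the ANCOVA model;
    with six decades there are C(6,2) = 15 contrasts and
    p_bonferroni = min(1, 15 * p_raw).
    """
    needed = ["age", outcome] + [c for c in covariates]
    df = _complete_cases(cohort, needed)
    y, X_full, _, levels = _ancova_design(df, outcome, covariates)
    fit = _ols(y, X_full)
    k = len(levels)
    n_contrasts = k * (k - 1) // 2

    rows = []
    for a, b in combinations(range(k), 2):
        c_vec = np.zeros(X_full.shape[1])
        # group coefficient indices: level 0 is the reference (coef 0)
        if a > 0:
            c_vec[a] = 1.0
        if b > 0:
            c_vec[b] = -1.0
        est = float(c_vec @ fit.beta)
        se = float(np.sqrt(c_vec @ fit.cov @ c_vec))
        t = est / se if se > 0 else 0.0
        p_raw = float(2 * sps.t.sf(abs(t), fit.df_resid))
        rows.append(
            {
                "group_a": levels[a],
                "group_b": levels[b],
                "estimate": est,
                "se": se,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, n_contrasts * p_raw),
            }
        )
    return PosthocTable(outcome=outcome, contrasts=pd.DataFrame(rows))


@dataclass
class DeltaR2Result:
    outcome: str
    block: str
    delta_r2: float
    lrt_stat: float
    lrt_p: float
    significant: bool
    n: int


def _base_design(df: pd.DataFrame, use_quad: bool) -> np.ndarray:
    age = df["age"].to_numpy(dtype=float)
    cols = [np.ones(len(df)), age]
    if use_quad:
        cols.append(age**2)
    cols += [_gender_indicator(df["gender"]), df["bmi"].to_numpy(dtype=float)]
    return np.column_stack(cols)


def incremental_block(
    cohort: pd.DataFrame,
    outcome: str,
    block: str,
    alpha: float = ALPHA,
    use_quad: bool | None = None,
) -> DeltaR2Result:
    """Delta R^2 and likelihood-ratio test for one predictor block.

    The block column (MET, MS_average or MS_diff) is added to the base
    model (age, optional quadratic age, gender, BMI).  Delta R^2 is on the
    unadjusted R^2 of nested OLS fits and is therefore always >= 0; the LRT
    compares Gaussian log-likelihoods (chi-squared, 1 df).
    """
    if block not in cohort.columns:
        raise ModelError(f"block column {block!r} missing from cohort table")
    df = _complete_cases(cohort, ["age", "gender", "bmi", outcome, block])
    y = df[outcome].to_numpy(dtype=float)
    if use_quad is None:
        res = fit_age_model(cohort, outcome, alpha=alpha)
        use_quad = res.quad_age is not None
    X_base = _base_design(df, use_quad)
    x_block = df[block].to_numpy(dtype=float)
    X_full = np.column_stack([X_base, x_block])

    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        logger.warning("%s + %s: block is collinear with the base model", outcome, block)
    fit_base = _ols(y, X_base)
    fit_full = _ols(y, X_full)
    delta_r2 = max(0.0, fit_full.r2 - fit_base.r2)
    lrt = 2.0 * (fit_full.llf - fit_base.llf)
    lrt_p = float(sps.chi2.sf(max(lrt, 0.0), 1))
    return DeltaR2Result(
        outcome=outcome,
        block=block,
        delta_r2=float(delta_r2),
        lrt_stat=float(max(lrt, 0.0)),
        lrt_p=lrt_p,
        significant=lrt_p < alpha,
        n=len(df),
    )


def muscle_specific_models(
    cohort: pd.DataFrame,
    outcome: str,
    muscle_groups,
    measure: str = "ms_average",
    alpha: float = ALPHA,
    use_quad: bool | None = None,
) -> pd.DataFrame:
    """Per-muscle-group association of strength with one outcome.

    For each muscle group the column ``{group}_{measure}`` is added to the
    base model; the table reports its coefficient, p value, sign, and a
    significance flag.  All-missing strength columns are flagged rather
    than raising.
    """
    if use_quad is None:
        res = fit_age_model(cohort, outcome, alpha=alpha)
        use_quad = res.quad_age is not None
    rows = []
    for grp in muscle_groups:
        col = f"{grp}_{measure}"
        if col not in cohort.columns or cohort[col].notna().sum() == 0:
            rows.append(
                {"muscle_group": grp, "measure": measure, "coef": np.nan, "se": np.nan,
                 "p": np.nan, "sign": "", "significant": False, "flag": "missing"}
            )
            continue
        df = _complete_cases(cohort, ["age", "gender", "bmi", outcome, col])
        y = df[outcome].to_numpy(dtype=float)
        X = np.column_stack([_base_design(df, use_quad), df[col].to_numpy(dtype=float)])
        fit = _ols(y, X)
        coef = float(fit.beta[-1])
        se = float(fit.se[-1])
        p = float(fit.t_pvalues()[-1])
        rows.append(
            {"muscle_group": grp, "measure": measure, "coef": coef, "se": se, "p": p,
             "sign": "+" if coef > 0 else "-", "significant": p < alpha, "flag": ""}
        )
    return pd.DataFrame(rows)
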