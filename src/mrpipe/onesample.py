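"""One-sample Mendelian randomization on individual-level data.

Implements the observational and instrumental-variable arms of a single-SNP
MR study: log-transform/standardization of the exposure, ordinary
least-squares regression, exactly-identified two-stage least squares (2SLS)
with first-stage diagnostics, the Durbin-Wu-Hausman endogeneity test in its
control-function form, and multinomial genotype-covariate balance tests.

All estimators take plain array-likes / DataFrames; covariates enter both
2SLS stages. Standard errors are classical (homoskedastic); 2SLS residuals
are formed with the *original* exposure, not the first-stage fitted values,
which is the correction that distinguishes proper IV standard errors from a
naive second-stage OLS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, EstimationError

__all__ = [
    "RegressionResult",
    "FirstStageDiagnostics",
    "DWHResult",
    "BalanceResult",
    "standardize_log_exposure",
    "ols_fit",
    "tsls_fit",
    "dwh_test",
    "covariate_balance",
]

logger = logging.getLogger(__name__)

#: conventional threshold below which an instrument is flagged as weak
WEAK_INSTRUMENT_F = 10.0


@dataclass(frozen=True)
class RegressionResult:
    """A single slope estimate with its classical inference."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    method_tag: str  # "OLS" or "2SLS"
    covariate_set: tuple[str, ...] = ()


@dataclass(frozen=True)
class FirstStageDiagnostics:
    """Instrument-strength summary from the first 2SLS stage."""

    f_statistic: float
    r2: float
    p_value: float


@dataclass(frozen=True)
class DWHResult:
    """Durbin-Wu-Hausman endogeneity test (control-function form)."""

    statistic: float
    df: tuple[int, int]
    p_value: float


@dataclass(frozen=True)
class BalanceResult:
    """Genotype-covariate balance p-values before/after ancestry adjustment."""

    covariate: str
    p_unadjusted: float
    p_adjusted: float  # NaN when no ancestry columns were supplied


# ---------------------------------------------------------------------------
# exposure transformation


def standardize_log_exposure(exposure_raw, grouping=None, ddof: int = 1) -> np.ndarray:
    """Natural-log transform a positive exposure and z-score it.

    The standardization uses the sample SD (``ddof=1``). When ``grouping``
    is given (e.g. sex labels), the z-score is computed within each group,
    matching the GWAS convention of sex-specific SD units; otherwise the
    whole vector is standardized at once.

    Raises
    ------
    DataError
        If any value is non-positive (identifying the first offending
        record) or a (group's) SD is zero.
    """
    x = np.asarray(exposure_raw, dtype=float)
    bad = np.where(~(x > 0))[0]
    if bad.size:
        raise DataError(
            f"exposure must be strictly positive; record {bad[0]} has value {x[bad[0]]!r}"
        )
    logx = np.log(x)

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise DataError("exposure has zero variance; cannot standardize")
        return (v - v.mean()) / sd

    if grouping is None:
        return _z(logx)
    g = np.asarray(grouping)
    if g.shape[0] != x.shape[0]:
        raise DataError("grouping must have the same length as the exposure")
    out = np.empty_like(logx)
    for level in pd.unique(g):
        mask = g == level
        out[mask] = _z(logx[mask])
    return out


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _as_matrix(covariates) -> tuple[np.ndarray, tuple[str, ...]]:
    if covariates is None:
        return np.empty((0, 0)), ()
    if isinstance(covariates, pd.DataFrame):
        names = tuple(str(c) for c in covariates.columns)
        return np.asarray(covariates, dtype=float), names
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def _design(n: int, covariates) -> tuple[np.ndarray, tuple[str, ...]]:
    """Intercept + covariate columns as a dense matrix."""
    cov, names = _as_matrix(covariates)
    if cov.size:
        if cov.shape[0] != n:
            raise DataError("covariates must have the same number of rows as the outcome")
        return np.column_stack([np.ones(n), cov]), names
    return np.ones((n, 1)), ()


def _check_full_rank(X: np.ndarray, colnames: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: the trailing pivots are the columns adding no direction
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dropped = sorted(colnames[j] for j in piv[rank:])
        raise EstimationError(
            f"design matrix is rank deficient; collinear column(s): {', '.join(dropped)}"
        )


def _slope_inference(
    beta: float, se: float, df_resid: int, n: int, tag: str, names: tuple[str, ...]
) -> RegressionResult:
    tq = stats.t.ppf(0.975, df_resid)
    if se > 0:
        p = 2.0 * stats.t.sf(abs(beta / se), df_resid)
    else:
        p = 0.0 if beta != 0 else 1.0
    return RegressionResult(
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - tq * se),
        ci_high=float(beta + tq * se),
        p_value=float(p),
        n=n,
        method_tag=tag,
        covariate_set=names,
    )


# ---------------------------------------------------------------------------
# estimators


def ols_fit(outcome, exposure_sd, covariates=None) -> RegressionResult:
    """OLS slope of the outcome on the (standardized) exposure.

    Classical standard errors; the 95% CI uses the t quantile with the
    residual degrees of freedom. Raises :class:`EstimationError` on a
    rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure_sd, dtype=float)
    n = y.shape[0]
    W, names = _design(n, covariates)
    X = np.column_stack([W, x])
    if n <= X.shape[1]:
        raise DataError(f"need n > {X.shape[1]} parameters, got n = {n}")
    _check_full_rank(X, ["const", *names, "exposure"])
    res = sm.OLS(y, X).fit()
    return _slope_inference(
        res.params[-1], res.bse[-1], int(res.df_resid), n, "OLS", names
    )


def tsls_fit(
    outcome, exposure_sd, instrument, covariates=None, robust: bool = False
) -> tuple[RegressionResult, FirstStageDiagnostics]:
    """Exactly-identified two-stage least squares.

    Stage one regresses the exposure on the instrument (plus covariates);
    stage two regresses the outcome on the stage-one prediction (plus
    covariates). The point estimate is the two-stage projection estimator;
    the error variance uses residuals formed with the *original* exposure.
    ``robust=True`` switches to an HC0 sandwich. Returns the slope result
    together with first-stage diagnostics (partial F and partial R-squared
    of the instrument). An F below 10 logs a weak-instrument warning.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure_sd, dtype=float)
    g = np.asarray(instrument, dtype=float)
    n = y.shape[0]
    if g.std() == 0:
        raise EstimationError("instrument is constant; 2SLS is not identified")
    W, names = _design(n, covariates)
    Z = np.column_stack([W, g])
    _check_full_rank(Z, ["const", *names, "instrument"])

    # first stage + partial F / partial R2 of the instrument
    fs = sm.OLS(x, Z).fit()
    xhat = fs.fittedvalues
    rss_full = float(fs.ssr)
    rss_reduced = float(sm.OLS(x, W).fit().ssr)
    df1 = n - Z.shape[1]
    f_stat = max(0.0, (rss_reduced - rss_full) / (rss_full / df1))
    partial_r2 = (rss_reduced - rss_full) / rss_reduced if rss_reduced > 0 else 0.0
    f_p = float(stats.f.sf(f_stat, 1, df1))
    diag = FirstStageDiagnostics(f_statistic=float(f_stat), r2=float(partial_r2), p_value=f_p)
    if f_stat < WEAK_INSTRUMENT_F:
        logger.warning(
            "weak instrument: first-stage partial F = %.2f (< %.0f)", f_stat, WEAK_INSTRUMENT_F
        )

    Xhat = np.column_stack([W, xhat])
    X = np.column_stack([W, x])
    XtX = Xhat.T @ Xhat
    try:
        beta = np.linalg.solve(XtX, Xhat.T @ y)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"2SLS normal equations are singular: {exc}") from None
    resid = y - X @ beta  # original exposure, not the plug-in
    k = X.shape[1]
    df_resid = n - k
    bread = np.linalg.inv(XtX)
    if robust:
        meat = Xhat.T @ (Xhat * resid[:, None] ** 2)
        cov = bread @ meat @ bread
    else:
        sigma2 = float(resid @ resid) / df_resid
        cov = sigma2 * bread
    se = math.sqrt(cov[-1, -1])
    return _slope_inference(beta[-1], se, df_resid, n, "2SLS", names), diag


def dwh_test(outcome, exposure_sd, instrument, covariates=None) -> DWHResult:
    """Durbin-Wu-Hausman exogeneity test via the control-function regression.

    The first-stage residual of the exposure on the instrument is added to
    the outcome OLS; the squared t statistic of its coefficient is reported
    as an F(1, n-k) test. A zero on that coefficient means the OLS and 2SLS
    slopes coincide. This augmented-regression form is asymptotically
    equivalent to the classical contrast (delta-beta over delta-variance)
    form but stays numerically stable when the variance difference is tiny.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure_sd, dtype=float)
    g = np.asarray(instrument, dtype=float)
    n = y.shape[0]
    W, names = _design(n, covariates)
    Z = np.column_stack([W, g])
    v = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    if float(v @ v) / n < 1e-12 * max(1.0, float(x @ x) / n):
        # exposure is an exact function of instrument+covariates: the two
        # estimators coincide and there is nothing to test
        return DWHResult(statistic=0.0, df=(1, n - W.shape[1] - 1), p_value=1.0)
    X = np.column_stack([W, x, v])
    _check_full_rank(X, ["const", *names, "exposure", "fs_resid"])
    res = sm.OLS(y, X).fit()
    t_v = res.params[-1] / res.bse[-1]
    stat = float(t_v**2)
    df = (1, int(res.df_resid))
    return DWHResult(statistic=stat, df=df, p_value=float(stats.f.sf(stat, *df)))


# ---------------------------------------------------------------------------
# genotype-covariate balance


def _encode_predictors(covariate) -> tuple[np.ndarray, int]:
    s = pd.Series(covariate)
    if s.dtype.kind in "biufc" and s.nunique() > 8:
        return s.to_numpy(dtype=float)[:, None], 1
    dummies = pd.get_dummies(s.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float), dummies.shape[1]


def _mnlogit_llf(endog: np.ndarray, exog: np.ndarray) -> float:
    model = sm.MNLogit(endog, exog)
    try:
        fit = model.fit(method="newton", maxiter=200, disp=0)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("newton did not converge")
    except Exception:
        fit = model.fit(method="bfgs", maxiter=500, disp=0)
    return float(fit.llf)


def covariate_balance(genotype, covariate, ancestry=None, name: str | None = None) -> BalanceResult:
    """Likelihood-ratio heterogeneity test of genotype class on a covariate.

    Genotype (0/1/2 dosage) is the multinomial outcome; the covariate (as
    dummies if categorical, linear if numeric with many levels) is the
    predictor. The reported p-value is the LR chi-squared comparing the model
    with and without the covariate terms; ``p_adjusted`` repeats the test
    with the ancestry columns included in both models (NaN when no ancestry
    is supplied). An empty genotype class collapses the model to two classes
    with a logged warning; a constant covariate returns p = 1 by convention.
    """
    g = np.asarray(genotype)
    labels, codes = np.unique(g, return_inverse=True)
    if labels.size < 2:
        raise DataError("genotype must have at least 2 observed classes")
    if labels.size == 2:
        logger.warning(
            "genotype has an empty class; collapsing to a 2-class (binary) model"
        )
    name = name or getattr(covariate, "name", None) or "covariate"

    pred, n_terms = _encode_predictors(covariate)
    if n_terms == 0 or np.allclose(pred.std(axis=0), 0):
        return BalanceResult(covariate=str(name), p_unadjusted=1.0, p_adjusted=1.0)
    n = codes.shape[0]
    const = np.ones((n, 1))

    def lr_p(extra_base: np.ndarray | None) -> float:
        base_cols = [const] if extra_base is None else [const, extra_base]
        base = np.hstack(base_cols)
        full = np.hstack([base, pred])
        stat = 2.0 * (_mnlogit_llf(codes, full) - _mnlogit_llf(codes, base))
        df = (labels.size - 1) * n_terms
        return float(stats.chi2.sf(max(stat, 0.0), df))

    p_unadj = lr_p(None)
    if ancestry is None:
        p_adj = float("nan")
    else:
        anc, _ = _as_matrix(ancestry)
        p_adj = lr_p(anc)
    return BalanceResult(covariate=str(name), p_unadjusted=p_unadj, p_adjusted=p_adj)
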