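"""Two-sample Mendelian randomization from GWAS summary statistics.

Operates on per-SNP panels (one row per SNP: effect allele, SD-unit exposure
beta, mm Hg outcome beta, standard errors — see
:data:`mrpipe.simulate.PANEL_COLUMNS`). Provides allele harmonization,
fixed-effects meta-analysis with Cochran's Q and I-squared, the single-SNP
Wald/IVW estimator, the multi-SNP inverse-variance-weighted (IVW) estimator,
and MR-Egger regression with percentile-bootstrap confidence intervals.

The IVW estimator follows the standard fixed-effects form

    beta = sum_k X_k Y_k / s_k^2  /  sum_k X_k^2 / s_k^2,
    se   = (sum_k X_k^2 / s_k^2)^(-1/2),

with X_k the SNP-exposure beta, Y_k the SNP-outcome beta and s_k the
SNP-outcome SE; the SNP-exposure SEs are ignored to first order (the usual
summary-data approximation). This is algebraically identical to an
inverse-variance meta-analysis of the per-SNP Wald ratios Y_k/X_k with SEs
s_k/|X_k|, and to weighted least squares of Y on X through the origin.
MR-Egger adds an intercept to that weighted regression: the intercept
estimates average directional pleiotropy and the slope remains a consistent
causal estimate under the InSIDE assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, EstimationError

__all__ = [
    "MREstimate",
    "MetaResult",
    "EggerResult",
    "harmonize",
    "fixed_effects_meta",
    "wald_ratios",
    "ivw_single",
    "ivw_multi",
    "egger_regression",
]

logger = logging.getLogger(__name__)

_PALINDROMIC = {frozenset("AT"), frozenset("CG")}
_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class MREstimate:
    """A summary-data causal-effect estimate (mm Hg per SD log-exposure)."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    method_tag: str  # "IVW_single", "IVW_multi" or "Egger_slope"


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects pooled estimate with heterogeneity statistics."""

    pooled_beta: float
    pooled_se: float
    q_statistic: float
    df: int
    i2: float  # percent, floored at 0
    p_heterogeneity: float


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger intercept/slope with percentile-bootstrap 95% CIs."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    n_snps: int
    n_boot: int
    seed: int | None


# ---------------------------------------------------------------------------
# harmonization


def harmonize(panel: pd.DataFrame) -> pd.DataFrame:
    """Orient every record to the exposure-increasing allele.

    Records with a negative SNP-exposure beta have their effect/other alleles
    swapped and *both* betas negated; standard errors are untouched. Records
    with a zero exposure beta are dropped (orientation undefined) with a
    logged reason. Palindromic (A/T, G/C) records are flagged in a
    ``palindromic`` column and logged but retained: without allele
    frequencies the strand cannot be inferred, and no exclusion rule is
    assumed.
    """
    out = panel.copy()
    zero = out["beta_exp"] == 0
    if zero.any():
        for snp in out.loc[zero, "snp"]:
            logger.info("dropping %s: beta_exp = 0, allele orientation undefined", snp)
        out = out.loc[~zero].copy()
    flip = (out["beta_exp"] < 0).to_numpy()
    ea = out["effect_allele"].to_numpy().copy()
    oa = out["other_allele"].to_numpy().copy()
    ea[flip], oa[flip] = oa[flip].copy(), ea[flip].copy()
    out["effect_allele"] = ea
    out["other_allele"] = oa
    out.loc[flip, ["beta_exp", "beta_out"]] *= -1.0
    out["palindromic"] = [
        frozenset((a, b)) in _PALINDROMIC for a, b in zip(out["effect_allele"], out["other_allele"])
    ]
    n_pal = int(out["palindromic"].sum())
    if n_pal:
        logger.warning("%d palindromic SNP(s) retained; strand not verifiable", n_pal)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# meta-analysis


def fixed_effects_meta(betas, ses) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling with Q and I-squared.

    ``pooled = sum(w b)/sum(w)`` with ``w = 1/se^2``;
    ``Q = sum w (b - pooled)^2``; ``I2 = max(0, (Q - df)/Q) * 100`` with
    ``df = k - 1``; the heterogeneity p-value is the chi-squared(df) upper
    tail. A single study pools to itself with Q = 0 and I2 = 0.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise DataError("fixed_effects_meta needs at least one study")
    if np.any(~(s > 0)):
        raise DataError("all standard errors must be > 0")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    if b.size == 1:
        logger.info("single-study meta-analysis: Q = 0, I2 reported as 0")
        return MetaResult(pooled, pooled_se, 0.0, 0, 0.0, 1.0)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = b.size - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, df))
    return MetaResult(pooled, pooled_se, q, df, i2, p_het)


# ---------------------------------------------------------------------------
# IVW estimators


def _normal_estimate(beta: float, se: float, k: int, tag: str) -> MREstimate:
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    return MREstimate(
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        p_value=float(p),
        n_snps=k,
        method_tag=tag,
    )


def wald_ratios(panel: pd.DataFrame, se_method: str = "ivw") -> pd.DataFrame:
    """Per-SNP ratio estimates Y/X with their approximate SEs.

    ``se_method="ivw"`` uses s_y/|X| (first order, SNP-exposure SE ignored);
    ``"delta"`` adds the SNP-exposure uncertainty:
    ``sqrt(s_y^2/X^2 + Y^2 s_x^2 / X^4)``.
    """
    x = panel["beta_exp"].to_numpy(dtype=float)
    y = panel["beta_out"].to_numpy(dtype=float)
    sy = panel["se_out"].to_numpy(dtype=float)
    if np.any(x == 0):
        raise EstimationError("beta_exp = 0: Wald ratio undefined; harmonize() drops these")
    ratio = y / x
    if se_method == "ivw":
        se = sy / np.abs(x)
    elif se_method == "delta":
        sx = panel["se_exp"].to_numpy(dtype=float)
        se = np.sqrt(sy**2 / x**2 + y**2 * sx**2 / x**4)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return pd.DataFrame({"snp": panel["snp"].to_numpy(), "ratio": ratio, "se": se})


def ivw_single(beta_exposure: float, beta_outcome: float, se_outcome: float) -> MREstimate:
    """Single-instrument Wald/IVW estimate: beta = Y/X, se = s_y/|X|.

    The 95% CI uses the 1.96 normal multiplier and the p-value a two-sided
    normal test, as appropriate for large-sample summary statistics.
    """
    if beta_exposure == 0:
        raise EstimationError("beta_exposure = 0: the Wald ratio is undefined")
    if se_outcome <= 0:
        raise DataError(f"se_outcome must be > 0, got {se_outcome}")
    beta = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    return _normal_estimate(beta, se, 1, "IVW_single")


def ivw_multi(panel: pd.DataFrame, se_method: str = "ivw") -> MREstimate:
    """Multi-SNP fixed-effects IVW estimate.

    Equals the inverse-variance meta-analysis of the per-SNP Wald ratios,
    and weighted least squares of Y on X through the origin with weights
    1/s_y^2. Requires a harmonized panel with at least two SNPs.
    """
    if len(panel) < 2:
        raise EstimationError("ivw_multi needs >= 2 SNPs; use ivw_single for one instrument")
    if (panel["beta_exp"] == 0).any():
        raise EstimationError("beta_exp = 0 in panel; run harmonize() first")
    if se_method == "ivw":
        x = panel["beta_exp"].to_numpy(dtype=float)
        y = panel["beta_out"].to_numpy(dtype=float)
        w = 1.0 / panel["se_out"].to_numpy(dtype=float) ** 2
        denom = float(np.sum(w * x**2))
        beta = float(np.sum(w * x * y)) / denom
        se = 1.0 / math.sqrt(denom)
    else:
        ratios = wald_ratios(panel, se_method=se_method)
        meta = fixed_effects_meta(ratios["ratio"], ratios["se"])
        beta, se = meta.pooled_beta, meta.pooled_se
    return _normal_estimate(beta, se, len(panel), "IVW_multi")


# ---------------------------------------------------------------------------
# MR-Egger


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Closed-form weighted least squares of y on x with intercept."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    slope = (w * (x - mx) * (y - my)).sum() / sxx
    return my - slope * mx, slope


def egger_regression(
    panel: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = None,
    scheme: str = "nonparametric",
) -> EggerResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas.

    The fit is weighted least squares with an intercept and weights
    1/s_y^2; it must be run on a *harmonized* panel because the estimates
    are not invariant to allele re-orientation once an intercept is present.
    95% CIs for intercept and slope come from a percentile bootstrap
    (default 10,000 iterations), deterministic for a fixed ``seed``.

    ``scheme`` selects the bootstrap:

    - ``"nonparametric"`` (default): resample the SNP records with
      replacement and refit;
    - ``"parametric"``: redraw Y_k ~ Normal(fitted_k, s_y,k) holding the
      SNP set fixed and refit.

    Analytic SEs from the weighted regression (with multiplicative
    overdispersion) are also reported for reference.
    """
    k = len(panel)
    if k < 3:
        raise EstimationError(f"MR-Egger needs >= 3 SNPs (intercept + slope), got {k}")
    if (panel["beta_exp"] < 0).any():
        raise DataError("panel must be harmonized before MR-Egger (negative beta_exp found)")
    x = panel["beta_exp"].to_numpy(dtype=float)
    y = panel["beta_out"].to_numpy(dtype=float)
    sy = panel["se_out"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise EstimationError("all exposure betas are equal; the Egger slope is unidentified")
    w = 1.0 / sy**2
    intercept, slope = _wls_line(x, y, w)

    # analytic reference SEs: weighted regression with dispersion >= 1
    resid = y - intercept - slope * x
    disp = max(1.0, float((w * resid**2).sum() / (k - 2)))
    sw = w.sum()
    mx = (w * x).sum() / sw
    sxx = float((w * (x - mx) ** 2).sum())
    slope_se = math.sqrt(disp / sxx)
    intercept_se = math.sqrt(disp * (1.0 / sw + mx**2 / sxx))

    if n_boot < 1:
        raise DataError(f"n_boot must be >= 1, got {n_boot}")
    rng = np.random.default_rng(seed)
    if scheme == "nonparametric":
        idx = rng.integers(0, k, size=(n_boot, k))
        xb, yb, wb = x[idx], y[idx], w[idx]
    elif scheme == "parametric":
        yb = intercept + slope * x + rng.normal(0.0, 1.0, size=(n_boot, k)) * sy
        xb = np.broadcast_to(x, (n_boot, k))
        wb = np.broadcast_to(w, (n_boot, k))
    else:
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")

    # vectorized closed-form WLS over bootstrap replicates
    swb = wb.sum(axis=1)
    mxb = (wb * xb).sum(axis=1) / swb
    myb = (wb * yb).sum(axis=1) / swb
    dx = xb - mxb[:, None]
    sxxb = (wb * dx**2).sum(axis=1)
    ok = sxxb > 0  # degenerate resamples (all one SNP) carry no slope information
    slopes = np.full(n_boot, np.nan)
    slopes[ok] = (wb * dx * (yb - myb[:, None])).sum(axis=1)[ok] / sxxb[ok]
    intercepts = myb - slopes * mxb
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropping %d degenerate bootstrap resample(s)", n_bad)
    lo_i, hi_i = np.nanpercentile(intercepts, [2.5, 97.5])
    lo_s, hi_s = np.nanpercentile(slopes, [2.5, 97.5])

    return EggerResult(
        intercept=float(intercept),
        slope=float(slope),
        intercept_se=float(intercept_se),
        slope_se=float(slope_se),
        intercept_ci=(float(lo_i), float(hi_i)),
        slope_ci=(float(lo_s), float(hi_s)),
        n_snps=k,
        n_boot=n_boot,
        seed=seed,
    )
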