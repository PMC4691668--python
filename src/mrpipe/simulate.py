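"""Synthetic data generators for Mendelian randomization analyses.

Two generators are provided:

``simulate_cohort``
    An individual-level birth-cohort table (genotype dosage, a positively
    skewed exposure concentration, systolic/diastolic blood pressure,
    covariates and an ancestry score), built around a single triallelic-coded
    SNP instrument acting additively on log-exposure, a latent standard-normal
    confounder loading on both exposure and outcomes, and optional
    population-stratification strata. Defaults are calibrated to a cohort of
    n = 3701 young adults in which the instrument explains about 5.3% of the
    variance in log-exposure (first-stage F around 200) and confounding
    induces an observational slope of roughly +1 mm Hg per SD of log-exposure
    while the true causal effect defaults to zero.

``simulate_two_sample_summary``
    A per-SNP GWAS summary panel (effect allele, SD-unit exposure beta,
    mm Hg outcome beta, standard errors) of the kind used in two-sample MR,
    with configurable directional pleiotropy, InSIDE violation, and a
    fraction of records deliberately stored on the exposure-decreasing allele
    so that harmonization is exercised downstream.

Both generators are deterministic for a fixed ``seed``; seeds are explicit
arguments, never global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "CohortConfig",
    "TwoSampleConfig",
    "simulate_cohort",
    "simulate_two_sample_summary",
    "solve_instrument_beta",
    "PANEL_COLUMNS",
]

#: canonical column order of a summary-statistic panel
PANEL_COLUMNS = [
    "snp",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
    "gene",
]

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the individual-level cohort generator.

    Parameters
    ----------
    n_individuals
        Cohort size after complete-case filtering (the generator emits no
        missing values).
    allele_freq
        Frequency of the exposure-increasing (T) allele in the base stratum.
        Genotypes are drawn from Hardy-Weinberg proportions.
    instrument_beta
        Additive per-allele effect on natural-log exposure, in the same units
        as ``noise_sd_x``. Ignored when ``target_r2`` is set.
    target_r2
        When not ``None``, the proportion of log-exposure variance the
        instrument should explain; ``instrument_beta`` is then solved
        analytically from the allele frequency and the non-genetic variance
        components (confounder, sex, residual).
    causal_beta
        True effect of a 1-SD increase in log-exposure on both blood-pressure
        outcomes, in mm Hg.
    confounder_beta_x, confounder_beta_y
        Loadings of a latent standard-normal confounder on log-exposure
        (log units) and on both outcomes (mm Hg).
    direct_snp_beta
        Horizontal-pleiotropy path: mm Hg per allele acting on the outcomes
        directly, not through the exposure.
    ancestry_strata
        Tuple of ``(proportion, allele_freq_offset, outcome_mean_offset)``
        triples describing discrete ancestry strata; proportions must sum
        to 1. A noisy per-individual ancestry score (``pc1``) standing in for
        genome-wide principal components is always emitted.
    noise_sd_x, noise_sd_y
        Residual SDs of log-exposure (log units) and of each outcome (mm Hg).
    sex_beta_x, sex_beta_sbp, sex_beta_dbp
        Male-minus-female differences in log-exposure and in the outcomes.
    covariate_stratum_assoc
        Probability that the categorical covariate column copies the stratum
        label instead of being drawn uniformly; 0 gives a covariate
        independent of everything (a balance-test null).
    seed
        Integer seed; the same config and seed give a byte-identical table.
    """

    n_individuals: int = 3701
    allele_freq: float = 0.306
    instrument_beta: float = 0.353
    target_r2: float | None = 0.053
    causal_beta: float = 0.0
    confounder_beta_x: float = 0.135
    confounder_beta_y: float = 2.5
    direct_snp_beta: float = 0.0
    ancestry_strata: tuple[tuple[float, float, float], ...] = ((1.0, 0.0, 0.0),)
    noise_sd_x: float = 0.416
    noise_sd_y: float = 12.0
    sex_beta_x: float = 0.045
    sex_beta_sbp: float = 12.2
    sex_beta_dbp: float = 4.4
    mean_log_exposure: float = math.log(8.0)
    sbp_mean: float = 117.4
    dbp_mean: float = 73.4
    covariate_stratum_assoc: float = 0.0
    ancestry_score_noise: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 10:
            raise ConfigError(f"n_individuals must be >= 10, got {self.n_individuals}")
        if not 0.0 < self.allele_freq < 1.0:
            raise ConfigError(f"allele_freq must lie in (0, 1), got {self.allele_freq}")
        if self.noise_sd_x <= 0:
            raise ConfigError(f"noise_sd_x must be > 0, got {self.noise_sd_x}")
        if self.noise_sd_y <= 0:
            raise ConfigError(f"noise_sd_y must be > 0, got {self.noise_sd_y}")
        if self.target_r2 is not None and not 0.0 < self.target_r2 < 1.0:
            raise ConfigError(f"target_r2 must lie in (0, 1), got {self.target_r2}")
        if self.ancestry_score_noise <= 0:
            raise ConfigError(
                f"ancestry_score_noise must be > 0, got {self.ancestry_score_noise}"
            )
        if not 0.0 <= self.covariate_stratum_assoc <= 1.0:
            raise ConfigError(
                f"covariate_stratum_assoc must lie in [0, 1], got {self.covariate_stratum_assoc}"
            )
        props = [s[0] for s in self.ancestry_strata]
        if not props or abs(sum(props) - 1.0) > 1e-8:
            raise ConfigError(
                f"ancestry_strata proportions must sum to 1, got {sum(props):g}"
            )
        for prop, df_off, _ in self.ancestry_strata:
            if prop <= 0:
                raise ConfigError(f"ancestry_strata proportion must be > 0, got {prop}")
            if not 0.0 < self.allele_freq + df_off < 1.0:
                raise ConfigError(
                    "ancestry_strata allele_freq_offset pushes the allele frequency "
                    f"outside (0, 1): {self.allele_freq + df_off:g}"
                )


def solve_instrument_beta(config: CohortConfig) -> float:
    """Per-allele effect giving the requested first-stage R-squared.

    With genotype variance v_g = 2q(1-q) and non-genetic log-exposure
    variance v_e, the instrument explains r2 = b^2 v_g / (b^2 v_g + v_e),
    hence b = sqrt(r2 v_e / ((1 - r2) v_g)). The base-stratum allele
    frequency is used; stratified designs perturb the realized R-squared
    slightly.
    """
    if config.target_r2 is None:
        return config.instrument_beta
    q = config.allele_freq
    v_g = 2.0 * q * (1.0 - q)
    v_e = (
        config.confounder_beta_x**2
        + config.sex_beta_x**2 / 4.0
        + config.noise_sd_x**2
    )
    return math.sqrt(config.target_r2 * v_e / ((1.0 - config.target_r2) * v_g))


def _log_exposure_sd(config: CohortConfig, beta_g: float) -> float:
    q = config.allele_freq
    v_g = 2.0 * q * (1.0 - q)
    return math.sqrt(
        beta_g**2 * v_g
        + config.confounder_beta_x**2
        + config.sex_beta_x**2 / 4.0
        + config.noise_sd_x**2
    )


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a complete individual-level cohort table.

    Returns a DataFrame with columns ``iid, genotype, exposure, sbp, dbp,
    sex, covar_cat, group, pc1``. ``genotype`` is the 0/1/2 dosage of the
    exposure-increasing allele drawn from per-stratum Hardy-Weinberg
    proportions; ``exposure`` is the raw positive concentration
    ``exp(mu + b_g*g + b_c*C + ...)``; outcomes add the causal effect of the
    (population-) standardized log-exposure, the confounder, any direct SNP
    effect, and the stratum offset. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    beta_g = solve_instrument_beta(config)

    props = np.array([s[0] for s in config.ancestry_strata])
    freq_off = np.array([s[1] for s in config.ancestry_strata])
    out_off = np.array([s[2] for s in config.ancestry_strata])
    stratum = rng.choice(len(props), size=n, p=props / props.sum())

    q_i = config.allele_freq + freq_off[stratum]
    genotype = rng.binomial(2, q_i)
    sex = rng.integers(0, 2, size=n)  # 1 = male
    sex_c = sex - 0.5
    confounder = rng.standard_normal(n)

    log_x = (
        config.mean_log_exposure
        + beta_g * (genotype - 2.0 * config.allele_freq)
        + config.sex_beta_x * sex_c
        + config.confounder_beta_x * confounder
        + rng.normal(0.0, config.noise_sd_x, size=n)
    )
    # causal dose is the population-standardized log exposure, so causal_beta
    # is exactly "mm Hg per SD of log exposure" under the generating model
    z_true = (log_x - config.mean_log_exposure) / _log_exposure_sd(config, beta_g)

    shared = (
        config.causal_beta * z_true
        + config.confounder_beta_y * confounder
        + config.direct_snp_beta * genotype
        + out_off[stratum]
    )
    sbp = (
        config.sbp_mean
        + config.sex_beta_sbp * sex_c
        + shared
        + rng.normal(0.0, config.noise_sd_y, size=n)
    )
    dbp = (
        config.dbp_mean
        + config.sex_beta_dbp * sex_c
        + shared
        + rng.normal(0.0, config.noise_sd_y, size=n)
    )

    # noisy ancestry score standing in for the leading genomic PC
    raw_score = stratum + rng.normal(0.0, config.ancestry_score_noise, size=n)
    pc1 = (raw_score - raw_score.mean()) / raw_score.std(ddof=1)

    n_cat = 4
    covar_cat = rng.integers(0, n_cat, size=n)
    if config.covariate_stratum_assoc > 0:
        copy = rng.random(n) < config.covariate_stratum_assoc
        covar_cat = np.where(copy, stratum % n_cat, covar_cat)

    return pd.DataFrame(
        {
            "iid": [f"P{i:05d}" for i in range(1, n + 1)],
            "genotype": genotype.astype(np.int64),
            "exposure": np.exp(log_x),
            "sbp": sbp,
            "dbp": dbp,
            "sex": sex.astype(np.int64),
            "covar_cat": pd.Categorical.from_codes(
                covar_cat, categories=[f"c{j}" for j in range(n_cat)]
            ).astype(str),
            "group": stratum.astype(np.int64),
            "pc1": pc1,
        }
    )


@dataclass(frozen=True)
class TwoSampleConfig:
    """Parameters of the two-sample GWAS summary-panel generator.

    ``beta_out`` for SNP *k* is generated as
    ``causal_beta * beta_exp_k + pleiotropy_k + Normal(0, se_outcome)``,
    where the pleiotropy term has mean ``pleiotropy_mean`` (non-zero mean =
    directional pleiotropy), SD ``pleiotropy_sd``, and correlation
    ``inside_violation`` with the exposure betas (0 = InSIDE holds). A
    fraction ``flip_fraction`` of records is stored on the
    exposure-decreasing allele to exercise harmonization.
    """

    n_snps: int = 18
    exposure_beta_range: tuple[float, float] = (0.03, 0.16)
    se_exposure: float = 0.008
    se_outcome: float = 0.10
    causal_beta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: float = 0.0
    flip_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.se_exposure <= 0:
            raise ConfigError(f"se_exposure must be > 0, got {self.se_exposure}")
        if self.se_outcome <= 0:
            raise ConfigError(f"se_outcome must be > 0, got {self.se_outcome}")
        if abs(self.inside_violation) > 1.0:
            raise ConfigError(
                f"inside_violation must lie in [-1, 1], got {self.inside_violation}"
            )
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ConfigError(f"flip_fraction must lie in [0, 1], got {self.flip_fraction}")
        lo, hi = self.exposure_beta_range
        if not lo < hi:
            raise ConfigError(f"exposure_beta_range must be increasing, got ({lo}, {hi})")


def simulate_two_sample_summary(config: TwoSampleConfig) -> pd.DataFrame:
    """Draw a per-SNP summary-statistic panel (one row per SNP).

    Columns follow :data:`PANEL_COLUMNS`. Exposure betas are uniform on
    ``exposure_beta_range`` (all positive on the exposure-increasing allele
    before any flip); pleiotropic direct effects get the requested mean, SD
    and correlation with the exposure betas. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    lo, hi = config.exposure_beta_range

    beta_exp = rng.uniform(lo, hi, size=k)
    if k > 1 and beta_exp.std() > 0:
        z_x = (beta_exp - beta_exp.mean()) / beta_exp.std()
    else:
        z_x = np.zeros(k)
    rho = config.inside_violation
    pleio = config.pleiotropy_mean + config.pleiotropy_sd * (
        rho * z_x + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(k)
    )
    beta_out = (
        config.causal_beta * beta_exp
        + pleio
        + rng.normal(0.0, config.se_outcome, size=k)
    )

    # allele pairs: two distinct nucleotides per SNP (palindromic pairs occur)
    a_idx = rng.integers(0, 4, size=k)
    b_idx = (a_idx + rng.integers(1, 4, size=k)) % 4
    effect = _NUCLEOTIDES[a_idx].copy()
    other = _NUCLEOTIDES[b_idx].copy()

    flip = rng.random(k) < config.flip_fraction
    beta_exp = np.where(flip, -beta_exp, beta_exp)
    beta_out = np.where(flip, -beta_out, beta_out)
    effect[flip], other[flip] = other[flip], effect[flip]

    return pd.DataFrame(
        {
            "snp": [f"rs{1000 + i}" for i in range(k)],
            "effect_allele": effect,
            "other_allele": other,
            "beta_exp": beta_exp,
            "se_exp": np.full(k, config.se_exposure),
            "beta_out": beta_out,
            "se_out": np.full(k, config.se_outcome),
            "gene": [f"G{i:02d}" for i in range(k)],
        }
    )
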