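"""Orchestration of the full analysis plan.

``run_pipeline`` executes, from a single :class:`AnalysisConfig`, the
enabled branches of the analysis plan: the one-sample arm (crude and
adjusted OLS, crude and ancestry-adjusted 2SLS with first-stage diagnostics
and the DWH test, genotype-covariate balance tests, optionally sex-
stratified) and the two-sample arm (harmonization, per-trait fixed-effects
meta-analysis with I-squared, single- and multi-SNP IVW, MR-Egger with
bootstrap CIs). ``render_report`` writes machine-readable results (JSON,
TSV) and the three figure types.

The report records a hash of the configuration and the seed, and the same
config + seed always reproduces numerically identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DataError, EstimationError
from .io import read_cohort, read_panel, write_cohort, write_panel
from .onesample import (
    covariate_balance,
    dwh_test,
    ols_fit,
    standardize_log_exposure,
    tsls_fit,
)
from .plots import plot_coefficients, plot_egger_scatter, plot_forest
from .simulate import CohortConfig, TwoSampleConfig, simulate_cohort, simulate_two_sample_summary
from .twosample import egger_regression, fixed_effects_meta, harmonize, ivw_multi, ivw_single

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline", "render_report", "ADJUSTMENT_PRESETS"]

logger = logging.getLogger(__name__)

#: named covariate sets forming the model ladder
ADJUSTMENT_PRESETS: dict[str, tuple[str, ...]] = {
    "crude": (),
    "pca": ("pc1",),
    "sociodemographic": ("sex", "covar_cat"),
    "full": ("sex", "covar_cat", "pc1"),
}

_MODES = ("onesample", "twosample", "both", "simulate")
_OUTCOMES = ("sbp", "dbp", "both")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to run (and re-run) one analysis."""

    mode: str = "simulate"
    cohort_path: str | None = None
    panel_sbp_path: str | None = None
    panel_dbp_path: str | None = None
    outcome: str = "both"
    adjustments: tuple[str, ...] = ("crude", "pca")
    by_sex: bool = False
    estimators: tuple[str, ...] = ("ols", "tsls", "dwh", "balance", "meta", "ivw", "egger")
    single_snp: str | None = None
    n_boot: int = 10_000
    seed: int | None = None
    output_dir: str = "mr_output"
    cohort_overrides: dict = field(default_factory=dict)
    panel_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.outcome not in _OUTCOMES:
            raise ConfigError(f"outcome must be one of {_OUTCOMES}, got {self.outcome!r}")
        for adj in self.adjustments:
            if adj not in ADJUSTMENT_PRESETS:
                raise ConfigError(
                    f"unknown adjustment preset {adj!r}; options: {tuple(ADJUSTMENT_PRESETS)}"
                )
        stochastic = self.mode == "simulate" or "egger" in self.estimators
        if stochastic and self.seed is None:
            raise ConfigError("seed is required when any stochastic step is enabled")
        if self.mode in ("onesample", "both") and self.cohort_path is None:
            raise ConfigError("cohort_path is required in one-sample modes")
        if self.mode in ("twosample", "both") and not (
            self.panel_sbp_path or self.panel_dbp_path
        ):
            raise ConfigError("a panel path is required in two-sample modes")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Ordered result blocks keyed by (outcome, method, adjustment, stratum)."""

    blocks: list[dict]
    panels: dict[str, list[dict]]
    provenance: dict

    def to_dict(self) -> dict:
        d = {"blocks": self.blocks, "panels": self.panels, "provenance": self.provenance}
        # normalize tuples -> lists so equality matches a JSON round trip
        return json.loads(json.dumps(d))

    def save_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load_json(cls, path) -> "AnalysisReport":
        d = json.loads(Path(path).read_text())
        return cls(blocks=d["blocks"], panels=d["panels"], provenance=d["provenance"])


def _block(outcome: str, method: str, adjustment: str, stratum: str, result, n: int) -> dict:
    return {
        "outcome": outcome,
        "method": method,
        "adjustment": adjustment,
        "stratum": stratum,
        "n": n,
        "result": dataclasses.asdict(result),
    }


def _covariate_matrix(df: pd.DataFrame, names: tuple[str, ...]) -> pd.DataFrame | None:
    if not names:
        return None
    cols = []
    for name in names:
        if name not in df.columns:
            raise DataError(f"adjustment covariate {name!r} not in cohort columns")
        col = df[name]
        if col.dtype.kind in "OUSb" or col.nunique() <= 8 and col.dtype.kind not in "fc":
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            if dummies.shape[1]:
                cols.append(dummies.astype(float))
        else:
            cols.append(col.astype(float).to_frame(name))
    return pd.concat(cols, axis=1) if cols else None


def _onesample_arm(cfg: AnalysisConfig, cohort: pd.DataFrame, blocks: list[dict]) -> None:
    outcomes = ("sbp", "dbp") if cfg.outcome == "both" else (cfg.outcome,)
    strata = {"all": cohort}
    if cfg.by_sex and "sex" in cohort.columns:
        strata["male"] = cohort[cohort["sex"] == 1]
        strata["female"] = cohort[cohort["sex"] == 0]

    for stratum, sub in strata.items():
        z = standardize_log_exposure(sub["exposure"].to_numpy())
        g = sub["genotype"].to_numpy()
        for outcome in outcomes:
            if outcome not in sub.columns:
                raise DataError(f"outcome column {outcome!r} not in cohort")
            y = sub[outcome].to_numpy(dtype=float)
            for adj in cfg.adjustments:
                names = ADJUSTMENT_PRESETS[adj]
                if stratum != "all":
                    names = tuple(n for n in names if n != "sex")
                cov = _covariate_matrix(sub, names)
                if "ols" in cfg.estimators:
                    res = ols_fit(y, z, cov)
                    blocks.append(_block(outcome, "OLS", adj, stratum, res, res.n))
                    logger.info("OLS %s/%s/%s: n=%d", outcome, adj, stratum, res.n)
                if "tsls" in cfg.estimators:
                    res, diag = tsls_fit(y, z, g, cov)
                    blocks.append(_block(outcome, "2SLS", adj, stratum, res, res.n))
                    blocks.append(_block(outcome, "first_stage", adj, stratum, diag, res.n))
                    logger.info(
                        "2SLS %s/%s/%s: n=%d F=%.1f R2=%.4f",
                        outcome, adj, stratum, res.n, diag.f_statistic, diag.r2,
                    )
                if "dwh" in cfg.estimators:
                    res = dwh_test(y, z, g, cov)
                    blocks.append(_block(outcome, "DWH", adj, stratum, res, len(sub)))
                    logger.info("DWH %s/%s/%s: n=%d p=%.3g", outcome, adj, stratum, len(sub), res.p_value)

    if "balance" in cfg.estimators:
        anc = cohort[["pc1"]] if "pc1" in cohort.columns else None
        for covar in ("sex", "covar_cat"):
            if covar not in cohort.columns:
                continue
            res = covariate_balance(cohort["genotype"], cohort[covar], anc, name=covar)
            blocks.append(_block("genotype", "balance", "crude", covar, res, len(cohort)))
            logger.info("balance %s: n=%d p=%.3g", covar, len(cohort), res.p_unadjusted)


def _twosample_arm(
    cfg: AnalysisConfig, panels: dict[str, pd.DataFrame], blocks: list[dict], kept: dict
) -> None:
    for outcome, raw in panels.items():
        panel = harmonize(raw)
        kept[outcome] = json.loads(panel.to_json(orient="records"))
        if "meta" in cfg.estimators:
            for trait, b_col, s_col in (
                (f"exposure_{outcome}", "beta_exp", "se_exp"),
                (outcome, "beta_out", "se_out"),
            ):
                meta = fixed_effects_meta(panel[b_col], panel[s_col])
                blocks.append(_block(trait, "meta", "crude", "all", meta, len(panel)))
                logger.info("meta %s: k=%d I2=%.0f%%", trait, len(panel), meta.i2)
        if "ivw" in cfg.estimators:
            row = None
            if cfg.single_snp is not None:
                match = panel[panel["snp"] == cfg.single_snp]
                if len(match):
                    row = match.iloc[0]
                else:
                    logger.warning("single_snp %s not in panel; using strongest instrument", cfg.single_snp)
            if row is None:
                row = panel.loc[panel["beta_exp"].idxmax()]
            res = ivw_single(float(row["beta_exp"]), float(row["beta_out"]), float(row["se_out"]))
            blocks.append(_block(outcome, "IVW_single", "crude", str(row["snp"]), res, 1))
            res = ivw_multi(panel)
            blocks.append(_block(outcome, "IVW_multi", "crude", "all", res, res.n_snps))
            logger.info("IVW %s: k=%d beta=%.3f", outcome, res.n_snps, res.beta)
        if "egger" in cfg.estimators:
            res = egger_regression(panel, n_boot=cfg.n_boot, seed=cfg.seed)
            blocks.append(_block(outcome, "Egger", "crude", "all", res, res.n_snps))
            logger.info("Egger %s: k=%d slope=%.3f intercept=%.3f", outcome, res.n_snps, res.slope, res.intercept)


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute the enabled analysis branches and collect an ordered report.

    In ``simulate`` mode the cohort and both outcome panels are generated
    (and written under the output directory as fixtures) before both arms
    run. Partial failures abort with the failing stage named; input files
    are never modified.
    """
    out_dir = Path(config.output_dir)
    (out_dir / "logs").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "logs" / "run.log", mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mrpipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: AnalysisConfig, out_dir: Path) -> AnalysisReport:
    blocks: list[dict] = []
    panels_kept: dict[str, list[dict]] = {}

    cohort = None
    panels: dict[str, pd.DataFrame] = {}

    if config.mode == "simulate":
        ccfg = CohortConfig(**{"seed": config.seed, **config.cohort_overrides})
        cohort = simulate_cohort(ccfg)
        write_cohort(cohort, out_dir / "fixtures" / "cohort.tsv")
        for i, outcome in enumerate(("sbp", "dbp")):
            pcfg = TwoSampleConfig(**{"seed": (config.seed or 0) + 1 + i, **config.panel_overrides})
            panels[outcome] = simulate_two_sample_summary(pcfg)
            write_panel(panels[outcome], out_dir / "fixtures" / f"panel_{outcome}.tsv")
        logger.info("simulated cohort n=%d and 2 panels k=%d", len(cohort), len(panels["sbp"]))
    else:
        if config.mode in ("onesample", "both"):
            cohort = read_cohort(config.cohort_path)
        if config.mode in ("twosample", "both"):
            if config.panel_sbp_path:
                panels["sbp"] = read_panel(config.panel_sbp_path)
            if config.panel_dbp_path:
                panels["dbp"] = read_panel(config.panel_dbp_path)

    try:
        if cohort is not None:
            _onesample_arm(config, cohort, blocks)
    except (DataError, EstimationError) as exc:
        raise type(exc)(f"one-sample stage failed: {exc}") from exc
    try:
        if panels:
            sel = {k: v for k, v in panels.items() if config.outcome in ("both", k)}
            _twosample_arm(config, sel or panels, blocks, panels_kept)
    except (DataError, EstimationError) as exc:
        raise type(exc)(f"two-sample stage failed: {exc}") from exc

    if not blocks:
        raise ConfigError("no analysis branch enabled; nothing to report")
    return AnalysisReport(
        blocks=blocks,
        panels=panels_kept,
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        },
    )


def render_report(report: AnalysisReport, output_dir) -> dict[str, Path]:
    """Write JSON + TSV results and the figures for a report.

    Returns a mapping of artifact names to paths. Raises on an empty report.
    """
    if not report.blocks:
        raise DataError("cannot render an empty report")
    out = Path(output_dir)
    (out / "results").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    json_path = out / "results" / "report.json"
    report.save_json(json_path)
    paths["report_json"] = json_path

    rows = []
    for blk in report.blocks:
        row = {k: blk[k] for k in ("outcome", "method", "adjustment", "stratum", "n")}
        for key, val in blk["result"].items():
            row[key] = json.dumps(val) if isinstance(val, (list, tuple)) else val
        rows.append(row)
    tsv_path = out / "results" / "estimates.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    paths["estimates_tsv"] = tsv_path

    coef_rows = [
        {
            "label": f"{b['outcome']} {b['method']} ({b['adjustment']}, {b['stratum']})",
            "beta": b["result"]["beta"],
            "ci_low": b["result"]["ci_low"],
            "ci_high": b["result"]["ci_high"],
        }
        for b in report.blocks
        if "beta" in b["result"] and "ci_low" in b["result"]
    ]
    for b in report.blocks:  # Egger slope rows carry their CI as a pair
        if b["method"] == "Egger":
            coef_rows.append(
                {
                    "label": f"{b['outcome']} Egger slope ({b['adjustment']})",
                    "beta": b["result"]["slope"],
                    "ci_low": b["result"]["slope_ci"][0],
                    "ci_high": b["result"]["slope_ci"][1],
                }
            )
    if coef_rows:
        p = out / "figures" / "coefficients.svg"
        plot_coefficients(coef_rows, p)
        paths["coefficients"] = p

    for outcome, records in report.panels.items():
        panel = pd.DataFrame(records)
        meta_blk = next(
            (b for b in report.blocks if b["method"] == "meta" and b["outcome"] == outcome), None
        )
        if meta_blk is not None:
            from .twosample import MetaResult

            meta = MetaResult(**meta_blk["result"])
            p = out / "figures" / f"forest_{outcome}.svg"
            plot_forest(panel, "beta_out", "se_out", meta, p, title=f"per-SNP effect on {outcome}")
            paths[f"forest_{outcome}"] = p
        ivw_blk = next(
            (b for b in report.blocks if b["method"] == "IVW_multi" and b["outcome"] == outcome), None
        )
        egger_blk = next(
            (b for b in report.blocks if b["method"] == "Egger" and b["outcome"] == outcome), None
        )
        if ivw_blk is not None and egger_blk is not None:
            from .twosample import EggerResult

            egger = EggerResult(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in egger_blk["result"].items()
            })
            p = out / "figures" / f"egger_scatter_{outcome}.svg"
            plot_egger_scatter(panel, ivw_blk["result"]["beta"], egger, p, title=outcome)
            paths[f"egger_scatter_{outcome}"] = p
    return paths
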