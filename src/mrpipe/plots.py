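"""Deterministic matplotlib figures for MR reports.

Three figure types: a coefficient dot-plot with 95% CIs across methods and
adjustment sets, a per-SNP forest plot with a pooled fixed-effects row and
an I-squared annotation, and an Egger-vs-IVW scatter of SNP-outcome against
SNP-exposure betas with both fitted lines. All plots use fixed ordering and
no jitter, so the same report always renders the same figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_coefficients", "plot_forest", "plot_egger_scatter"]


def plot_coefficients(rows: list[dict], path=None):
    """Dot-plot of slope estimates with 95% CIs, one row per analysis block.

    ``rows`` are dicts with keys ``label, beta, ci_low, ci_high``.
    """
    fig, ax = plt.subplots(figsize=(7, 0.45 * max(4, len(rows)) + 1))
    ys = np.arange(len(rows))[::-1]
    for y, row in zip(ys, rows):
        ax.plot([row["ci_low"], row["ci_high"]], [y, y], color="0.3", lw=1.4)
        ax.plot(row["beta"], y, "o", color="C0", ms=5)
    ax.axvline(0.0, color="0.7", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([r["label"] for r in rows], fontsize=8)
    ax.set_xlabel("mm Hg per SD log-exposure (95% CI)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_forest(panel: pd.DataFrame, value_col: str, se_col: str, meta, path=None, title: str = ""):
    """Forest plot: one row per SNP plus a pooled fixed-effects row.

    ``meta`` is a :class:`mrpipe.twosample.MetaResult`; its I-squared and
    heterogeneity p-value are annotated on the pooled row.
    """
    k = len(panel)
    fig, ax = plt.subplots(figsize=(7, 0.35 * (k + 1) + 1.2))
    ys = np.arange(k + 1)[::-1]
    betas = panel[value_col].to_numpy(dtype=float)
    ses = panel[se_col].to_numpy(dtype=float)
    for y, b, s in zip(ys[:-1], betas, ses):
        ax.plot([b - 1.96 * s, b + 1.96 * s], [y, y], color="0.3", lw=1.2)
        ax.plot(b, y, "s", color="C0", ms=4)
    pb, ps = meta.pooled_beta, meta.pooled_se
    ax.plot([pb - 1.96 * ps, pb + 1.96 * ps], [ys[-1], ys[-1]], color="C3", lw=2.0)
    ax.plot(pb, ys[-1], "D", color="C3", ms=6)
    labels = list(panel["snp"].astype(str)) + [
        f"Pooled (I² = {meta.i2:.0f}%, P-het = {meta.p_heterogeneity:.2g})"
    ]
    ax.set_yticks(ys)
    ax.set_yticklabels(labels, fontsize=8)
    ax.axvline(0.0, color="0.7", lw=0.8, ls="--")
    ax.set_xlabel("per-allele effect (95% CI)")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_egger_scatter(panel: pd.DataFrame, ivw_beta: float, egger, path=None, title: str = ""):
    """SNP-outcome vs SNP-exposure betas with IVW and Egger fitted lines.

    The IVW line passes through the origin (dashed); the Egger line carries
    the pleiotropy intercept (solid).
    """
    x = panel["beta_exp"].to_numpy(dtype=float)
    y = panel["beta_out"].to_numpy(dtype=float)
    sy = panel["se_out"].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.errorbar(x, y, yerr=1.96 * sy, fmt="o", color="C0", ms=4, lw=0.8, capsize=2)
    xs = np.linspace(0.0, float(x.max()) * 1.05, 50)
    ax.plot(xs, ivw_beta * xs, "--", color="C1", label="IVW")
    ax.plot(xs, egger.intercept + egger.slope * xs, "-", color="C3", label="MR-Egger")
    ax.axhline(0.0, color="0.8", lw=0.6)
    ax.set_xlabel("SNP-exposure beta (SD per allele)")
    ax.set_ylabel("SNP-outcome beta (mm Hg per allele)")
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
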