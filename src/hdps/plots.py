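"""Figure rendering for the HDPS diagnostics.

Each function takes the tidy table produced by the corresponding
:mod:`hdps.diagnostics` operation and returns a matplotlib Figure styled
after the conventional displays: identity and prevalence-ratio 0.5/2.0
dashed bands on the prevalence scatter, 10% dashed reference lines on ASD
plots, and colour-coding by data dimension where applicable.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from hdps.diagnostics import ASD_REFERENCE, PR_BAND


def _dimension_colors(dimensions) -> dict:
    cmap = plt.get_cmap("tab10")
    return {d: cmap(i % 10) for i, d in enumerate(pd.unique(dimensions))}


def plot_concept_summary(summary: pd.DataFrame):
    """Horizontal bar chart of covariate counts per (dimension, chapter)."""
    fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * len(summary))))
    colors = _dimension_colors(summary["dimension"])
    labels = summary["dimension"] + " / " + summary["chapter"]
    ax.barh(labels, summary["n"], color=[colors[d] for d in summary["dimension"]])
    ax.set_xlabel("selected covariates")
    ax.set_title("High-level concepts in the selected HDPS covariates")
    fig.tight_layout()
    return fig


def plot_ps_overlap(overlap: dict):
    """Mirrored PS histograms per exposure group, one panel per model."""
    models = list(overlap["densities"])
    fig, axes = plt.subplots(1, len(models), figsize=(6 * len(models), 4), sharey=True)
    axes = np.atleast_1d(axes)
    centers = (overlap["grid"][:-1] + overlap["grid"][1:]) / 2
    for ax, model in zip(axes, models):
        d = overlap["densities"][model]
        ax.fill_between(centers, d[1], step="mid", alpha=0.5, label="exposed")
        ax.fill_between(centers, -d[0], step="mid", alpha=0.5, label="unexposed")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(f"{model} (overlap {overlap['overlap'][model]:.2f})")
        ax.set_xlabel("propensity score")
        ax.legend()
    axes[0].set_ylabel("density (unexposed mirrored)")
    fig.tight_layout()
    return fig


def plot_prevalence_scatter(scatter: pd.DataFrame):
    """Group prevalences with identity and PR 0.5/2.0 dashed bands."""
    fig, ax = plt.subplots(figsize=(6, 6))
    colors = _dimension_colors(scatter["dimension"])
    for dim, sub in scatter.groupby("dimension"):
        ax.scatter(sub["pc0"], sub["pc1"], s=14, alpha=0.7, label=dim, color=colors[dim])
    lim = max(scatter["pc1"].max(), scatter["pc0"].max()) * 1.05 + 1e-6
    grid = np.linspace(0, lim, 50)
    ax.plot(grid, grid, "k-", lw=0.8)
    for pr in PR_BAND:
        ax.plot(grid, pr * grid, "k--", lw=0.8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("prevalence, unexposed")
    ax.set_ylabel("prevalence, exposed")
    ax.set_title("Covariate prevalence by treatment group (dashed: PR 0.5 / 2.0)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_balance(balance: pd.DataFrame, weight_labels: list[str] | None = None):
    """Unweighted vs weighted ASDs with 10% dashed reference lines."""
    if weight_labels is None:
        weight_labels = [c[len("asd_"):] for c in balance.columns if c.startswith("asd_")]
    fig, ax = plt.subplots(figsize=(6, 6))
    for wl in weight_labels:
        ax.scatter(balance["asd_unweighted"], balance[f"asd_{wl}"], s=14, alpha=0.7, label=wl)
    ax.axhline(ASD_REFERENCE, ls="--", c="k", lw=0.8)
    ax.axvline(ASD_REFERENCE, ls="--", c="k", lw=0.8)
    ax.set_xlabel("unweighted ASD (%)")
    ax.set_ylabel("weighted ASD (%)")
    ax.set_title("Covariate balance before and after weighting (dashed: 10%)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_bias_distribution(dist: pd.DataFrame):
    """|log Bross bias| against rank, colour-coded by dimension."""
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = _dimension_colors(dist["dimension"])
    for dim, sub in dist.groupby("dimension"):
        ax.scatter(sub["rank"], sub["abs_log_bias"], s=10, label=dim, color=colors[dim])
    ax.set_xlabel("Bross rank")
    ax.set_ylabel("|log bias|")
    ax.set_title("Distribution of absolute log Bross bias values")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_association_scatter(scatter: pd.DataFrame):
    """Exposure vs outcome association strengths; near-IVs highlighted."""
    fig, ax = plt.subplots(figsize=(6, 6))
    flagged = scatter["near_iv_relaxed"]
    ax.scatter(
        scatter.loc[~flagged, "strength_outcome"],
        scatter.loc[~flagged, "strength_exposure"],
        s=14, alpha=0.7, label="covariates",
    )
    if flagged.any():
        ax.scatter(
            scatter.loc[flagged, "strength_outcome"],
            scatter.loc[flagged, "strength_exposure"],
            s=30, marker="x", color="red", label="near-IV (relaxed rule)",
        )
    ax.set_xlabel("|RR(covariate-outcome) - 1|")
    ax.set_ylabel("|RR(covariate-exposure) - 1|")
    ax.set_title("Covariate-exposure vs covariate-outcome association strength")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_sensitivity_trace(curve: pd.DataFrame, true_log_hr: float | None = None):
    """Log HR (with CI) against the number of HDPS covariates selected."""
    fig, ax = plt.subplots(figsize=(7, 4))
    k = curve["k"]
    ax.plot(k, curve["log_hr"], "o-", ms=4)
    ax.fill_between(
        k, np.log(curve["ci_lower"]), np.log(curve["ci_upper"]), alpha=0.2
    )
    if true_log_hr is not None:
        ax.axhline(true_log_hr, ls="--", c="k", lw=0.8, label="truth")
        ax.legend()
    ax.set_xlabel("number of HDPS covariates selected (k)")
    ax.set_ylabel("log hazard ratio")
    ax.set_title("Effect estimate vs number of covariates selected")
    fig.tight_layout()
    return fig
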