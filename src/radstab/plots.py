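"""Figure emission for every pipeline stage (matplotlib, file output)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stability import CATEGORIES, HEATMAP_CAP, HISTOGRAM_BINS
from .survival import significance_stars


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def category_fractions_bar(summary: pd.DataFrame, path) -> None:
    """Stacked bar chart of stability-category fractions per group."""
    groups = summary["group"].unique()
    fig, ax = plt.subplots(figsize=(max(6, len(groups)), 4))
    bottom = np.zeros(len(groups))
    for cat in CATEGORIES:
        vals = [
            summary[(summary["group"] == g) & (summary["category"] == cat)]["fraction"].sum() for g in groups
        ]
        ax.bar(range(len(groups)), vals, bottom=bottom, label=cat)
        bottom += np.asarray(vals)
    ax.set_xticks(range(len(groups)), groups, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("fraction of features")
    ax.legend(fontsize=7)
    _save(fig, path)


def cov_histogram(summary: pd.DataFrame, path) -> None:
    """Five-bin histogram of population mean COV."""
    counts = summary["bin"].value_counts().reindex(HISTOGRAM_BINS).fillna(0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(range(len(HISTOGRAM_BINS)), counts.to_numpy())
    ax.set_xticks(range(len(HISTOGRAM_BINS)), [f"COV{b}%" for b in HISTOGRAM_BINS], rotation=30)
    ax.set_ylabel("feature count")
    _save(fig, path)


def cov_heatmap(table, path) -> None:
    """Individual-COV heatmap: patients (by motion) x clustered features."""
    from .stability import cov_heatmap_order

    feat_order, pat_order = cov_heatmap_order(table)
    data = table.individual_cov.loc[pat_order, feat_order].to_numpy()
    data = np.where(np.isnan(data), HEATMAP_CAP, np.minimum(data, HEATMAP_CAP))
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(data, aspect="auto", cmap="RdYlGn_r", vmin=0, vmax=HEATMAP_CAP)
    ax.set_yticks(range(len(pat_order)), pat_order, fontsize=6)
    ax.set_xlabel("features (complete-linkage order)")
    ax.set_ylabel("patients (by motion magnitude)")
    fig.colorbar(im, label="COV (%)")
    _save(fig, path)


def cohort_heatmap(features: pd.DataFrame, assignment, clinical: pd.DataFrame, path) -> None:
    """Patient-clustered expression heatmap with clinical tracks."""
    order = assignment.patient_order
    cols = assignment.stable_feature_order + assignment.unstable_feature_order
    X = features.loc[order, cols].to_numpy(float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    fig, axes = plt.subplots(
        2, 1, figsize=(9, 6), height_ratios=[4, 1], sharex=False
    )
    im = axes[0].imshow(X.T, aspect="auto", cmap="coolwarm", vmin=-2.5, vmax=2.5)
    if assignment.stable_feature_order:
        axes[0].axhline(len(assignment.stable_feature_order) - 0.5, color="k", lw=1)
    axes[0].set_ylabel("features (stable | unstable)")
    fig.colorbar(im, ax=axes[0], label="z-score")
    codes = clinical.loc[order].apply(lambda c: pd.factorize(c)[0])
    axes[1].imshow(codes.T.to_numpy(), aspect="auto", cmap="tab10", interpolation="nearest")
    axes[1].set_yticks(range(len(clinical.columns)), clinical.columns, fontsize=7)
    axes[1].set_xlabel("patients (cluster order)")
    _save(fig, path)


def chi2_boxplot(evaluations: dict[str, np.ndarray], comparison_p: dict[str, float], path) -> None:
    """Boxplot of per-round OOB logrank chi2 per configuration with
    significance stars vs. the unfiltered model."""
    labels = list(evaluations)
    data = [np.asarray(evaluations[k])[np.isfinite(evaluations[k])] for k in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.boxplot(data, tick_labels=labels, whis=(0, 100))
    for i, lab in enumerate(labels):
        p = comparison_p.get(lab)
        if p is not None and data[i].size:
            ax.text(i + 1, data[i].max(), significance_stars(p), ha="center", va="bottom")
    ax.set_ylabel(r"logrank $\chi^2$ (OOB)")
    _save(fig, path)


def km_curves(time, event, high_risk, path, title: str = "") -> None:
    """Kaplan-Meier curves of the predicted low/high-risk groups."""
    from lifelines import KaplanMeierFitter

    from .coxlib import logrank_chi2

    fig, ax = plt.subplots(figsize=(5, 4))
    kmf = KaplanMeierFitter()
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g = np.asarray(high_risk, bool)
    for sel, lab in ((~g, "low risk"), (g, "high risk")):
        if sel.any():
            kmf.fit(t[sel], e[sel], label=lab)
            kmf.plot_survival_function(ax=ax)
    chi2 = logrank_chi2(g, t, e)
    ax.set_title(f"{title} logrank chi2 = {chi2:.2f}".strip())
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    _save(fig, path)
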