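"""Figure builders for the evaluation and parsimony outputs.

All functions build standalone :class:`matplotlib.figure.Figure` objects
(no pyplot state, safe headless) and return them; callers save with
``fig.savefig(path)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .evaluation import EvaluationReport

__all__ = [
    "plot_roc_curves",
    "plot_calibration",
    "plot_representative_distributions",
    "plot_parsimony",
]

_SCORE_LABELS = {
    "lasso_mu": "Model (predicted rate)",
    "history_of_falls": "History of falls",
    "gait_speed": "Gait speed",
    "sppb": "SPPB",
    "external_score": "External risk score",
}


def plot_roc_curves(report: EvaluationReport) -> Figure:
    """ROC curves of all scores, one panel per outcome."""
    fig = Figure(figsize=(10, 4.5))
    axes = fig.subplots(1, 2)
    for ax, outcome, title in zip(
        axes, ("fallers", "multiple_fallers"), ("Single falls", "Multiple falls")
    ):
        for (score, o), res in sorted(report.aucs.items()):
            if o != outcome:
                continue
            ax.plot(
                res.curve[:, 0],
                res.curve[:, 1],
                label=f"{_SCORE_LABELS.get(score, score)} (AUC {res.auc:.3f})",
                lw=1.2,
            )
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(title)
        ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    return fig


def plot_calibration(report: EvaluationReport) -> Figure:
    """Reliability diagram, marginal calibration plot, and PIT histogram."""
    fig = Figure(figsize=(13, 4))
    ax_rel, ax_marg, ax_pit = fig.subplots(1, 3)

    rel = report.calibration.reliability
    ax_rel.errorbar(
        rel["mean_predicted"],
        rel["mean_observed"],
        yerr=rel["ci_half_width"],
        fmt="o",
        ms=4,
        capsize=3,
    )
    lim = max(rel["mean_predicted"].max(), rel["mean_observed"].max()) * 1.1
    ax_rel.plot([0, lim], [0, lim], "k:", lw=0.8)
    ax_rel.set_xlabel("Predicted fall rate")
    ax_rel.set_ylabel("Observed fall rate")
    ax_rel.set_title("Reliability diagram")

    marg = report.calibration.marginal
    width = 0.4
    ax_marg.bar(marg["k"] - width / 2, marg["observed"], width, label="observed")
    ax_marg.bar(marg["k"] + width / 2, marg["predicted"], width, label="predicted")
    ax_marg.set_xlabel("Number of falls")
    ax_marg.set_ylabel("Number of samples")
    ax_marg.set_title("Marginal calibration")
    ax_marg.legend(fontsize=8)

    pit = report.calibration.pit
    J = len(pit)
    ax_pit.bar(np.arange(J) / J, pit, width=1 / J, align="edge", edgecolor="white")
    ax_pit.axhline(1 / J, color="k", ls=":", lw=0.8)
    ax_pit.set_xlabel("PIT")
    ax_pit.set_ylabel("Relative frequency")
    ax_pit.set_title("Probability integral transform")

    fig.tight_layout()
    return fig


def plot_representative_distributions(rows: list[dict], pooled: np.ndarray) -> Figure:
    """Predictive pmfs at risk-score percentiles vs the pooled observed counts."""
    fig = Figure(figsize=(7, 4.5))
    ax = fig.subplots()
    ks = np.arange(len(pooled))
    ax.bar(ks, pooled, width=0.8, color="0.8", label="observed (all samples)")
    for row in rows:
        ax.plot(
            np.arange(len(row["pmf"])),
            row["pmf"],
            marker="o",
            ms=3,
            lw=1,
            label=f"{row['percentile']:g}th pct (E[falls]={row['mu']:.2f})",
        )
    ax.set_xlabel("Number of falls")
    ax.set_ylabel("Probability")
    ax.set_title("Representative predictive distributions")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_parsimony(curve: pd.DataFrame) -> Figure:
    """AUC and MSE against the model-size cap, with mean model size overlaid."""
    fig = Figure(figsize=(10, 4.5))
    ax_auc, ax_mse = fig.subplots(1, 2)
    ax_auc.plot(curve["n"], curve["auc_single"], "o-", mfc="none", color="k",
                ms=4, lw=1, label="AUC single falls")
    ax_auc.plot(curve["n"], curve["auc_multiple"], "o-", color="k",
                ms=4, lw=1, label="AUC multiple falls")
    ax_auc.set_xlabel("Maximum number of covariates n")
    ax_auc.set_ylabel("AUC")
    ax_auc.legend(fontsize=8, loc="lower right")
    ax_mse.plot(curve["n"], curve["mse"], "o-", color="k", ms=4, lw=1, label="MSE")
    ax_mse.set_xlabel("Maximum number of covariates n")
    ax_mse.set_ylabel("MSE")
    for ax in (ax_auc, ax_mse):
        twin = ax.twinx()
        twin.plot(curve["n"], curve["mean_active"], "o-", color="tab:blue",
                  ms=3, lw=1, alpha=0.7)
        twin.set_ylabel("Mean covariates used", color="tab:blue")
        twin.tick_params(axis="y", colors="tab:blue")
    fig.tight_layout()
    return fig
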