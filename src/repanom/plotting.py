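"""Diagnostic plots: the three-panel anomaly view and ROC curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluate import RocResult
from .pipeline import AnomalyReport

__all__ = ["plot_report", "plot_roc"]


def plot_report(
    report: AnomalyReport,
    features_flat: np.ndarray | None = None,
    events=(),
    path=None,
):
    """Three stacked panels: extracted phase + ACMP + phase score, scaled
    reconstruction errors, and (optionally) the normalized features."""
    n_panels = 3 if features_flat is not None else 2
    fig, axes = plt.subplots(n_panels, 1, figsize=(12, 2.6 * n_panels), sharex=True)
    t = np.arange(len(report))

    ax = axes[0]
    ax.plot(t, report.raw_phase.angles, ".", ms=1.5, color="lightblue", label="extracted phase")
    ax.plot(t, report.acmp, ".", ms=1.5, color="black", label="ACMP phase")
    ax.plot(t, report.phase_score, color="red", lw=0.8, label="phase score")
    ax.set_ylabel("phase [rad]")
    ax.legend(loc="upper right", fontsize=7)

    ax = axes[1]
    for k, name in enumerate(report.channel_names):
        ax.plot(t, report.recon_scores[:, k], lw=0.7, label=name)
    ax.set_ylabel("scaled recon. error")
    ax.legend(loc="upper right", fontsize=6, ncol=3)

    if features_flat is not None:
        ax = axes[2]
        ax.plot(t, features_flat, lw=0.6)
        ax.set_ylabel("normalized features")

    for ax in axes:
        for s, e, *_ in events:
            ax.axvspan(s, e, color="gold", alpha=0.3)
    axes[-1].set_xlabel("frame")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_roc(results: dict[str, RocResult], path=None):
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, res in results.items():
        ax.plot(res.frontier[:, 0], res.frontier[:, 1], marker="o", ms=3,
                label=f"{label} (AUC={res.auc:.4f})")
        ax.plot(res.best["fpr"], res.best["tpr"], "o", color="orange", ms=8, mfc="none")
    ax.plot([0, 1], [0, 1], ":", color="gray", lw=0.8)
    ax.set_xlabel("false positive rate (periods)")
    ax.set_ylabel("true positive rate (events)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
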