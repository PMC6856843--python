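"""Plots of fitted accuracy against threshold and on the ROC plane."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .study_data import DISEASE_FREE, MetaDataset
from .summaries import AccuracyCurve


def plot_accuracy_curves(curve: AccuracyCurve, path=None):
    """Two panels: summary tpr and fpr across thresholds with 95% bands.

    Credible bands are shaded; prediction bands, when present, are drawn
    as dashed envelopes.
    """
    fig, axes = plt.subplots(2, 1, figsize=(7, 8), sharex=True)
    panels = [
        ("tpr", curve.tpr_summary, curve.tpr_cri, curve.tpr_pi),
        ("fpr", curve.fpr_summary, curve.fpr_cri, curve.fpr_pi),
    ]
    for ax, (name, mid, cri, pi) in zip(axes, panels):
        ax.fill_between(curve.thresholds, cri[0], cri[1], alpha=0.3, label="95% CrI")
        ax.plot(curve.thresholds, mid, lw=2, label=f"summary {name}")
        if pi is not None:
            ax.plot(curve.thresholds, pi[0], "--", color="gray", label="95% PI")
            ax.plot(curve.thresholds, pi[1], "--", color="gray")
        ax.set_xscale("log")
        ax.set_ylim(0, 1)
        ax.set_ylabel(name)
        ax.legend(loc="best", fontsize=8)
    axes[1].set_xlabel("threshold")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_sroc(curve: AccuracyCurve, dataset: MetaDataset | None = None, path=None):
    """Summary ROC curve, optionally with the observed study points."""
    fig, ax = plt.subplots(figsize=(6, 6))
    if dataset is not None:
        for sid in dataset.study_ids:
            free = dataset.record(sid, DISEASE_FREE)
            dis = dataset.record(sid, 2)
            common = np.intersect1d(free.thresholds, dis.thresholds)
            if common.size == 0:
                continue
            f = [free.counts_above[np.flatnonzero(free.thresholds == c)[0]] / free.n
                 for c in common]
            t = [dis.counts_above[np.flatnonzero(dis.thresholds == c)[0]] / dis.n
                 for c in common]
            ax.plot(f, t, "o-", color="lightsteelblue", ms=3, lw=0.8)
    ax.plot(curve.fpr_summary, curve.tpr_summary, "k-", lw=2, label="summary ROC")
    ax.plot([0, 1], [0, 1], ":", color="gray")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
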