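"""Matplotlib payloads for the standard report figures."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def phantom_bar_chart(table, out_path=None):
    """Per-site phantom ADC bar chart (raw vs temperature-corrected)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(table))
    ax.bar(x - 0.2, table["central_mean_raw"], 0.4, label="raw",
           yerr=table.get("central_within_roi_sd"), capsize=3)
    ax.bar(x + 0.2, table["central_mean_20c"], 0.4, label="corrected to 20 °C")
    ax.set_xticks(x, table["site"])
    ax.set_ylabel("phantom ADC (μm²/s)")
    ax.legend()
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def bland_altman_plot(result, ylabel="relative difference (%)", out_path=None):
    fig, ax = plt.subplots(figsize=(7, 4))
    pairs = result.pairs
    for site, grp in pairs.groupby("site"):
        ax.scatter(grp["pair_mean"], grp["rel_diff_pct"], label=str(site), s=18)
    ax.axhline(result.mean_diff_pct, color="b", ls=":")
    for y in result.loa:
        ax.axhline(y, color="r", ls=":")
    ax.set_xlabel("pair mean")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def roc_plot(roc, out_path=None):
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc["fpr_grid"], roc["mean_tpr"],
            label=f"mean AUC {roc['mean_auc']:.2f} ± {roc['sd_auc']:.2f}")
    ax.fill_between(roc["fpr_grid"], roc["mean_tpr"] - roc["sd_tpr"],
                    np.minimum(roc["mean_tpr"] + roc["sd_tpr"], 1), alpha=0.2)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend()
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def distance_heatmap(dm, out_path=None):
    order = np.argsort([str(k) for k in dm.labels])
    mat = dm.normalized[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="viridis")
    fig.colorbar(im, ax=ax, label="normalized 1-Wasserstein distance")
    names = [str(dm.labels[i]) for i in order]
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=5)
    ax.set_yticks(range(len(names)), names, fontsize=5)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def tsne_scatter(coords, classes, out_path=None):
    fig, ax = plt.subplots(figsize=(5, 5))
    classes = np.asarray(classes)
    for cls in np.unique(classes):
        sel = classes == cls
        ax.scatter(coords[sel, 0], coords[sel, 1], label=str(cls), s=20)
    ax.set_xlabel("tSNE 1 (arbitrary units)")
    ax.set_ylabel("tSNE 2 (arbitrary units)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
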