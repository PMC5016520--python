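"""Static plots: rejection curves, z/p scatters, synthesis bars, CDR panels.

All functions draw on a supplied matplotlib Axes (created when absent)
and return it, so figures compose and save the usual way.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster import hierarchy

__all__ = [
    "plot_rejection_curves",
    "plot_scatter",
    "plot_synthesis",
    "plot_length_distribution",
    "plot_variability",
    "plot_stacked_classes",
    "plot_association_heatmap",
]

_PROC_COLORS = {
    "rawp": "black",
    "bonferroni": "tab:red",
    "holm": "tab:orange",
    "hochberg": "tab:olive",
    "sidakSS": "tab:green",
    "sidakSD": "tab:cyan",
    "BH": "tab:blue",
    "BY": "tab:purple",
}


def _ax(ax):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    return ax


def plot_rejection_curves(curves, ax=None):
    """Rejected hypotheses against alpha, one line per procedure."""
    ax = _ax(ax)
    for c in curves:
        ax.plot(c.alphas, c.n_rejected, label=c.procedure,
                color=_PROC_COLORS.get(c.procedure), lw=1.4)
    ax.set_xlabel(r"$\alpha$ (type I error rate)")
    ax.set_ylabel("rejected null hypotheses")
    ax.legend(fontsize=8)
    return ax


def plot_scatter(scatter_df, alpha=0.05, ax=None):
    """-log10 p against z; raw p black, each adjusted family coloured."""
    ax = _ax(ax)
    df = scatter_df.dropna(subset=["z"])
    for col, label in [("neglog10_rawp", "rawp")] + [
        (f"neglog10_{p}", p) for p in _PROC_COLORS if p != "rawp"
    ]:
        if col in df:
            ax.scatter(df["z"], df[col], s=12, label=label,
                       color=_PROC_COLORS.get(label), alpha=0.75)
    ax.axhline(-np.log10(alpha), ls="--", c="grey", lw=0.8)
    ax.axvline(1.96, ls=":", c="grey", lw=0.8)
    ax.axvline(-1.96, ls=":", c="grey", lw=0.8)
    ax.set_xlabel("z")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(fontsize=7)
    return ax


def plot_synthesis(synth_df, model, ax=None):
    """Normalised per-10,000 usage bars for both sets plus the difference CI."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(7, 0.25 * len(synth_df)), 5))
    x = np.arange(len(synth_df))
    w = 0.4
    ax.bar(x - w / 2, synth_df["norm1"], width=w, label=model.set1.label)
    ax.bar(x + w / 2, synth_df["norm2"], width=w, label=model.set2.label)
    sig = synth_df[[c for c in synth_df.columns if c.startswith("sig_")]].all(axis=1)
    for xi, flag in zip(x, sig):
        if flag:
            top = max(synth_df["norm1"].iloc[xi], synth_df["norm2"].iloc[xi])
            ax.annotate("*", (xi, top), ha="center", fontsize=11)
    ax.set_xticks(x)
    ax.set_xticklabels(synth_df["item"], rotation=90, fontsize=7)
    ax.set_ylabel("per 10,000")
    ax.legend()
    return ax


def plot_length_distribution(dist, ax=None):
    """Side-by-side CDR length histogram for the two sets."""
    ax = _ax(ax)
    frame = dist.to_frame()
    x = frame["length"].to_numpy()
    w = 0.4
    ax.bar(x - w / 2, frame[dist.labels[0]], width=w, label=dist.labels[0])
    ax.bar(x + w / 2, frame[dist.labels[1]], width=w, label=dist.labels[1])
    ax.set_xlabel(f"CDR{dist.cdr_type} length (AA)")
    ax.set_ylabel("per 10,000" if dist.normalized else dist.mode)
    ax.legend()
    return ax


def plot_variability(profile, index: str = "shannon", ax=None):
    """One variability index across IMGT positions of one CDR length."""
    ax = _ax(ax)
    vals = profile.indices.loc[index].astype(float)
    ax.plot(range(len(profile.positions)), vals.to_numpy(), marker="o")
    if index == "shannon":
        ax.axhline(2.0, ls="--", c="grey", lw=0.8)  # variable above
        ax.axhline(1.0, ls=":", c="grey", lw=0.8)   # conserved below
    ax.set_xticks(range(len(profile.positions)))
    ax.set_xticklabels(profile.positions, rotation=90, fontsize=7)
    ax.set_xlabel("IMGT position")
    ax.set_ylabel(index)
    return ax


def plot_stacked_classes(profile, ax=None):
    """Stacked class counts per IMGT position."""
    ax = _ax(ax)
    bottom = np.zeros(len(profile.positions))
    x = np.arange(len(profile.positions))
    for cls in profile.counts.index:
        vals = profile.counts.loc[cls].to_numpy(dtype=float)
        ax.bar(x, vals, bottom=bottom, label=str(cls))
        bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels(profile.positions, rotation=90, fontsize=7)
    ax.legend(fontsize=6, ncol=2)
    return ax


def plot_association_heatmap(assoc, fig=None):
    """Heatmap of a gene-association matrix with dendrogram margins."""
    if fig is None:
        fig = plt.figure(figsize=(9, 8))
    table = assoc.reordered()
    gs = fig.add_gridspec(
        2, 2, width_ratios=[1, 5], height_ratios=[1, 5], wspace=0.02, hspace=0.02
    )
    ax_col = fig.add_subplot(gs[0, 1])
    ax_row = fig.add_subplot(gs[1, 0])
    ax_hm = fig.add_subplot(gs[1, 1])
    if assoc.col_linkage is not None:
        hierarchy.dendrogram(assoc.col_linkage, ax=ax_col, no_labels=True,
                             link_color_func=lambda _: "k")
    if assoc.row_linkage is not None:
        hierarchy.dendrogram(assoc.row_linkage, ax=ax_row, orientation="left",
                             no_labels=True, link_color_func=lambda _: "k")
    ax_col.axis("off")
    ax_row.axis("off")
    im = ax_hm.imshow(table.to_numpy(), aspect="auto", cmap="viridis")
    ax_hm.set_xticks(range(len(table.columns)))
    ax_hm.set_xticklabels(table.columns, rotation=90, fontsize=7)
    ax_hm.set_yticks(range(len(table.index)))
    ax_hm.set_yticklabels(table.index, fontsize=6)
    ax_hm.yaxis.tick_right()
    fig.colorbar(im, ax=ax_hm, shrink=0.6)
    return fig
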