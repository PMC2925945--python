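"""Exploratory plots for the array stage.

Matplotlib figures mirroring the two standard views of a discovery run:
the invasive vs non-invasive mean-beta scatter, and the class-mean
heatmap of a fitted beta-mixture tree.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_invasive_scatter", "plot_class_heatmap"]


def plot_invasive_scatter(beta, invasive, ax=None):
    """Scatter of per-locus mean beta in non-invasive (x) vs invasive (y)
    tumors; points above the diagonal are hypermethylated with invasion."""
    import matplotlib.pyplot as plt

    invasive = np.asarray(invasive).astype(bool)
    x = beta.loc[~invasive].mean(axis=0)
    y = beta.loc[invasive].mean(axis=0)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=8, alpha=0.6, edgecolors="none")
    ax.plot([0, 1], [0, 1], lw=1, color="0.4")
    ax.set_xlabel("mean beta, non-invasive")
    ax.set_ylabel("mean beta, invasive")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def plot_class_heatmap(rpmm_results, ax=None, max_loci: int = 200):
    """Heatmap of per-class mean methylation (loci as rows, one column per
    methylation class, column width proportional to class size)."""
    import matplotlib.pyplot as plt

    tree = rpmm_results.tree
    means = np.column_stack(
        [lp["a"] / (lp["a"] + lp["b"]) for lp in tree.leaf_params]
    )  # (J, L)
    order = np.argsort(means.mean(axis=1))[::-1][:max_loci]
    means = means[order]
    masses = np.array([lp["mass"] for lp in tree.leaf_params])
    widths = np.maximum((masses / masses.sum() * 100).astype(int), 1)
    img = np.repeat(means, widths, axis=1)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(img, aspect="auto", cmap="YlGnBu", vmin=0, vmax=1)
    edges = np.cumsum(widths)[:-1]
    for e in edges:
        ax.axvline(e - 0.5, color="red", lw=1)
    ax.set_xticks([])
    ax.set_ylabel("locus (sorted by mean methylation)")
    ax.set_xlabel("methylation class (width = class size)")
    return ax
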