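"""Optional matplotlib views of the main results.

Imported lazily so the core pipeline has no hard plotting dependency;
install the ``plot`` extra (or matplotlib) to use these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def waterfall_plot(scores: pd.Series, ax=None):
    """Bar chart of methylation scores sorted descending; sign colors calls."""
    plt = _pyplot()
    ax = ax or plt.gca()
    ordered = scores.sort_values(ascending=False)
    colors = ["firebrick" if v > 0 else "steelblue" for v in ordered]
    ax.bar(range(len(ordered)), ordered.to_numpy(), color=colors, width=0.9)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("samples (ranked)")
    ax.set_ylabel("methylation score")
    return ax


def brier_curve_plot(mean_brier: pd.Series, ax=None):
    """Mean Brier score against candidate panel size."""
    plt = _pyplot()
    ax = ax or plt.gca()
    ax.plot(mean_brier.index, mean_brier.to_numpy(), marker="o")
    best = mean_brier.idxmin()
    ax.axvline(best, color="grey", ls="--", lw=0.8, label=f"selected size {best}")
    ax.set_xlabel("panel size")
    ax.set_ylabel("mean Brier score")
    ax.legend()
    return ax


def consensus_heatmap(consensus: pd.DataFrame, assignments: pd.Series | None = None, ax=None):
    """Consensus matrix ordered by cluster assignment (white=0, dark=1)."""
    plt = _pyplot()
    ax = ax or plt.gca()
    order = list(consensus.index)
    if assignments is not None:
        order = list(assignments.sort_values().index)
    arr = consensus.loc[order, order].to_numpy()
    im = ax.imshow(arr, vmin=0, vmax=1, cmap="Blues", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(im, ax=ax, label="consensus")
    return ax


def roc_plot(points: pd.DataFrame, auc: float | None = None, ax=None):
    """ROC curve from the (fpr, tpr) table returned by roc_auc."""
    plt = _pyplot()
    ax = ax or plt.gca()
    label = None if auc is None else f"AUC = {auc:.3f}"
    ax.plot(points["fpr"], points["tpr"], label=label)
    ax.plot([0, 1], [0, 1], color="grey", ls=":", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend()
    return ax


def cdf_plot(cdf_per_k: dict[int, pd.DataFrame], ax=None):
    """Empirical consensus CDFs for each k (the curves behind delta-area)."""
    plt = _pyplot()
    ax = ax or plt.gca()
    for k, table in sorted(cdf_per_k.items()):
        xs = np.concatenate([[0.0], table["consensus"].to_numpy(), [1.0]])
        ys = np.concatenate([[0.0], table["cdf"].to_numpy(), [1.0]])
        ax.step(xs, ys, where="post", label=f"k={k}")
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend()
    return ax
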