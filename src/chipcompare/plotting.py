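"""Optional figure rendering (heatmap, ROC, ECDF). The tested artifacts are
the matrices and tables; these helpers only draw them."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_signal_heatmap(matrix, path: str, log_scale: bool = True) -> None:
    values = matrix.values
    if log_scale:
        values = np.log1p(values)
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(values, aspect="auto", interpolation="nearest", cmap="Reds", origin="lower")
    ax.set_xlabel(f"position around TSS (bin = {matrix.bin_size} bp)")
    ax.set_ylabel("genes (ascending expression)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curves: dict, path: str) -> None:
    """curves: name -> ROCCurve."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for name, roc in sorted(curves.items()):
        pts = roc.points.sort_values(["x", "y"])
        x = np.concatenate([[0.0], pts["x"], [1.0]])
        y = np.concatenate([[0.0], pts["y"], [1.0]])
        ax.plot(x, y, marker="o", ms=3, label=f"{name} (AUC = {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ecdf(comparisons: dict, path: str) -> None:
    """comparisons: name -> ECDFComparison."""
    fig, axes = plt.subplots(1, len(comparisons), figsize=(4 * len(comparisons), 3.5))
    if len(comparisons) == 1:
        axes = [axes]
    for ax, (name, cmp_) in zip(axes, sorted(comparisons.items())):
        ax.step(cmp_.support, cmp_.bg_cdf, where="post", label="background")
        ax.step(cmp_.support, cmp_.fg_cdf, where="post", label="foreground")
        ax.axvline(cmp_.d_location, c="gray", ls=":", lw=0.8)
        ax.set_title(f"{name} (d = {cmp_.d:.2f})", fontsize=9)
        ax.set_xlabel("promoter signal (RPM)")
        ax.set_ylabel("cumulative frequency")
        ax.set_xscale("symlog")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
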