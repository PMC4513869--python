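"""Plot helpers for metagene profiles and condition summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .gene_context import MetageneProfile  # noqa: E402

__all__ = ["plot_metagene", "plot_condition_summary"]


def plot_metagene(
    ip: MetageneProfile, input_: MetageneProfile, path: str | None = None
):
    """Metagene density of IP and input across flank/body/flank segments."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(3 * ip.n_bins)
    ax.plot(x, ip.concatenated(), label="IP", color="firebrick")
    ax.plot(x, input_.concatenated(), label="input", color="steelblue")
    for b in (ip.n_bins, 2 * ip.n_bins):
        ax.axvline(b - 0.5, color="grey", lw=0.5, ls=":")
    ax.set_xticks([ip.n_bins / 2, 1.5 * ip.n_bins, 2.5 * ip.n_bins])
    ax.set_xticklabels(["Overlap Start", "Inside", "Overlap End"])
    ax.set_ylabel("(reads / nt) / total reads")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_condition_summary(summary: pd.DataFrame, path: str | None = None):
    """Bar chart of corrected m6A/A means with SD error bars per condition."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(summary["condition"].astype(str), summary["mean"],
           yerr=summary["sd"], capsize=4, color="slategray")
    ax.set_ylabel("m6A/A (corrected)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
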