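"""Manhattan-style delta-index plots and trait histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_scan(results, path=None, chroms: Optional[Sequence[str]] = None):
    """Per-chromosome delta-index panels: sites, window mean, CI envelope."""
    model = results.model
    names = list(chroms or model.chrom_sizes)
    fig, axes = plt.subplots(
        len(names), 1, figsize=(9, 2.2 * len(names)), squeeze=False, sharey=True
    )
    pct = int(round(results.level * 100))
    for ax, chrom in zip(axes[:, 0], names):
        rec = results.records[results.records["chrom"] == chrom]
        win = results.windows[results.windows["chrom"] == chrom]
        ax.scatter(rec["pos"] / 1e6, rec["delta"], s=2, alpha=0.25, color="grey")
        mid = (win["start"] + win["end"]) / 2e6
        ax.plot(mid, win["mean_delta"], color="crimson", lw=1.2, label="window mean")
        if f"ci{pct}_low" in win:
            ax.plot(mid, win[f"ci{pct}_low"], color="steelblue", lw=0.8)
            ax.plot(
                mid, win[f"ci{pct}_high"], color="steelblue", lw=0.8, label=f"{pct}% CI"
            )
        ax.axhline(0, color="black", lw=0.5)
        ax.set_ylabel(f"$\\Delta$ index\n{chrom}")
        ax.set_ylim(-1, 1)
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)
    return fig


def plot_trait_hist(values, trait: str = "", bins: int = 15, path=None):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(values, float), bins=bins, color="steelblue", edgecolor="white")
    ax.set_xlabel(trait)
    ax.set_ylabel("number of lines")
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)
    return fig
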