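"""Scatter and Bland-Altman plots for paired-volume comparisons."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import PairedVolumes, bland_altman, pearson_ci


def scatter_plot(pairs: PairedVolumes, path: str | Path) -> Path:
    """Volumes of method B against method A with the identity line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs.a, pairs.b, c="tab:blue", edgecolors="k", zorder=3)
    lim = (0, max(pairs.a.max(), pairs.b.max()) * 1.05 + 1)
    ax.plot(lim, lim, "k--", lw=1, label="identity")
    try:
        r, _, _, _ = pearson_ci(pairs)
        ax.set_title(f"r = {r:.2f}")
    except ValueError:
        pass
    ax.set_xlim(lim), ax.set_ylim(lim)
    ax.set_xlabel(f"{pairs.method_a} volume (ml)")
    ax.set_ylabel(f"{pairs.method_b} volume (ml)")
    ax.legend(loc="lower right")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def bland_altman_plot(pairs: PairedVolumes, path: str | Path) -> Path:
    """Paired differences against means, with bias and limits of agreement."""
    bias, loa, _ = bland_altman(pairs)
    means = (pairs.a + pairs.b) / 2.0
    diffs = pairs.a - pairs.b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, c="tab:blue", edgecolors="k", zorder=3)
    ax.axhline(bias, color="k", label=f"bias {bias:.2f} ml")
    for v in loa:
        ax.axhline(v, color="k", ls="--", lw=1)
    ax.set_xlabel(f"mean of {pairs.method_a} and {pairs.method_b} (ml)")
    ax.set_ylabel(f"{pairs.method_a} − {pairs.method_b} (ml)")
    ax.legend(loc="upper right")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
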