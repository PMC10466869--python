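"""Plotting helpers: genome-wide scan plot and enrichment charts."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def scan_plot(records, regions, threshold: float, path) -> None:
    """Manhattan-style plot: dots = per-site ED^power, line = fitted curve,
    dashed line = association threshold, shaded spans = called regions."""
    chroms = []
    for r in records:
        if not chroms or chroms[-1] != r.chrom:
            chroms.append(r.chrom)
    offsets = {}
    running = 0
    for c in chroms:
        offsets[c] = running
        running += max(r.pos for r in records if r.chrom == c) + 1

    x = np.array([offsets[r.chrom] + r.pos for r in records])
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.scatter(x, [r.ed4 for r in records], s=4, alpha=0.4, label="ED$^4$")
    ax.plot(x, [r.fitted for r in records], color="C1", lw=1.2, label="fitted")
    ax.axhline(threshold, color="C3", ls="--", lw=1, label="Median + 3SD")
    for reg in regions:
        ax.axvspan(
            offsets[reg.chrom] + reg.start, offsets[reg.chrom] + reg.end,
            color="C0", alpha=0.15,
        )
    ax.set_xticks([offsets[c] + max(r.pos for r in records if r.chrom == c) / 2 for c in chroms])
    ax.set_xticklabels(chroms)
    ax.set_ylabel("ED$^4$")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def enrichment_bubble(results: Sequence, path, top: int = 20) -> None:
    """Bubble chart of the top enriched terms: x = rich factor, bubble size =
    candidate genes in the term, colour = q-value."""
    results = list(results)[:top]
    if not results:
        return
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(results) + 1.5))
    y = np.arange(len(results))[::-1]
    sc = ax.scatter(
        [r.rich_factor for r in results], y,
        s=[40 + 25 * r.m for r in results],
        c=[r.q_value for r in results], cmap="viridis_r",
    )
    ax.set_yticks(y)
    ax.set_yticklabels([r.term_name for r in results], fontsize=8)
    ax.set_xlabel("rich factor (m/M)")
    fig.colorbar(sc, ax=ax, label="q-value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
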