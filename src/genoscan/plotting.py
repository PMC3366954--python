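"""Genome-wide score track, one point per window.

Chromosomes are laid end to end on the x axis; the y axis is the capped
log10(1/p) enrichment score. A horizontal line marks the significance
threshold (score 3 = corrected probability 0.001 by default), so spikes
above the line are clusters unlikely to occur by chance.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from genoscan.scan import ScanResult, chrom_sort_key


def plot_score_track(
    result: ScanResult,
    threshold: float = 3.0,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Plot the per-genome enrichment score track.

    Returns the matplotlib axes (created on a new figure when ``ax`` is
    None) so callers can save or further style the plot.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    df = result.to_frame()
    chroms = sorted(df["chrom"].unique(), key=chrom_sort_key)
    offset = 0
    ticks, labels = [], []
    for i, chrom in enumerate(chroms):
        sub = df[df["chrom"] == chrom]
        x = sub["center_bp"].to_numpy() + offset
        color = "#1f77b4" if i % 2 == 0 else "#7fb3d5"
        ax.vlines(x, 0, sub["score"].to_numpy(), color=color, linewidth=0.8)
        ticks.append(offset + sub["center_bp"].max() / 2)
        labels.append(chrom)
        offset += int(sub["center_bp"].max()) + result.params.step_bp
    ax.axhline(threshold, color="black", linewidth=1.0)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel(r"$\log_{10}(p^{-1})$")
    ax.set_ylim(0, result.params.score_cap * 1.05)
    ax.set_xlim(0, offset)
    return ax
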