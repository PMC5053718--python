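"""Optional figure output for profiles (SVG/PNG via matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metagene import MetageneProfile


def plot_metagene(
    profiles: dict[str, MetageneProfile], path, ylabel: str = "density"
) -> None:
    """Line plot of one or more metagene profiles sharing a layout, with
    segment boundaries marked."""
    fig, ax = plt.subplots(figsize=(7, 3))
    first = next(iter(profiles.values()))
    for label, prof in profiles.items():
        ax.plot(prof.values, label=label, lw=1)
    acc = 0
    for seg in first.spec.segments[:-1]:
        acc += seg.n_bins
        ax.axvline(acc, color="grey", ls=":", lw=0.8)
    ticks, acc = [], 0
    for seg in first.spec.segments:
        ticks.append((acc + seg.n_bins / 2, seg.name))
        acc += seg.n_bins
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([n for _, n in ticks])
    ax.set_ylabel(f"{ylabel} ({first.unit})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_site_profile(profile: pd.DataFrame, path) -> None:
    """Mean +/- SEM footprint density around site centers."""
    fig, ax = plt.subplots(figsize=(5, 3))
    x = profile["offset"].to_numpy()
    m = profile["mean"].to_numpy()
    s = profile["sem"].to_numpy()
    ax.plot(x, m, color="tab:blue", lw=1.2)
    ax.fill_between(x, m - s, m + s, color="tab:blue", alpha=0.3, lw=0)
    ax.axvline(0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("offset from site center (nt)")
    ax.set_ylabel("footprint density (CPM)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
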