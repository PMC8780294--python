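"""Minimal plotting helpers (Manhattan-style window plots, LD decay)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .genotype_io import GenomeLayout

__all__ = ["manhattan_windows", "ld_decay_plot"]


def manhattan_windows(scores: pd.DataFrame, layout: GenomeLayout, path) -> None:
    """One dot per window at its genome-cumulative midpoint, coloured by sequence."""
    offsets = {}
    cum = 0
    for name, length in layout.lengths.items():
        offsets[name] = cum
        cum += length
    fig, ax = plt.subplots(figsize=(10, 3))
    valid = scores[~scores["fst"].isna()]
    x = valid["chrom"].map(offsets).to_numpy() + (
        valid["start"].to_numpy() + valid["end"].to_numpy()
    ) / 2
    color_idx = valid["chrom"].map(
        {n: i % 2 for i, n in enumerate(layout.lengths)}
    )
    ax.scatter(x, valid["fst"], s=4, c=np.where(color_idx == 0, "#33537d", "#8aa3c4"))
    ax.set_xlabel("genome position")
    ax.set_ylabel("window mean $F_{ST}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ld_decay_plot(bins_by_breed: dict[str, pd.DataFrame], path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for breed, bins in bins_by_breed.items():
        ok = bins["n_pairs"] > 0
        ax.plot(bins.loc[ok, "mean_dist"] / 1000, bins.loc[ok, "mean_r2"],
                label=breed, lw=1)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
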