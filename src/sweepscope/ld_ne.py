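"""Linkage-disequilibrium decay and LD-based effective population size.

r^2 between two SNPs is the squared sample correlation of their dosage
vectors over co-called individuals (composite genotype r^2 — no phasing).
Pairs are restricted to the same chromosome and to distances below a maximum
(default 300 kb for decay curves), and aggregated into contiguous distance
bins (default 50 kb wide, half-open).

Effective population size follows the Sved relationship between expected r^2
and recombination distance c (Morgans):

    E[r^2] = 1 / (alpha + 4 Ne c) + 1/n

so that, per distance bin,

    r2_adj = mean r^2 - 1/n
    t      = 1 / (2 c)                (generations ago)
    Ne     = (1 / (4 c)) * (1 / r2_adj - alpha)

with c = mean pair distance x 1e-8 (a fixed 1 cM/Mb map) and alpha = 2.2 by
default (2 gives the textbook Sved form; 2.2 adds the mutation correction).
Bins where the inversion yields a non-positive Ne are flagged undefined rather
than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

__all__ = ["LdNeConfig", "ld_decay", "ne_from_ld", "expected_r2"]

DEFAULT_MAX_DIST = 300_000
DEFAULT_BIN_WIDTH = 50_000


@dataclass(frozen=True)
class LdNeConfig:
    alpha: float = 2.2
    recomb_rate_cm_per_mb: float = 1.0
    sample_size_adjust: bool = True

    @property
    def morgans_per_bp(self) -> float:
        return self.recomb_rate_cm_per_mb * 1e-8


def _pairwise_r2_block(
    x: np.ndarray, block: np.ndarray
) -> np.ndarray:
    """r^2 of one dosage vector against a block of vectors, pairwise-complete.

    Missing entries are NaN; each pair uses only co-called individuals.
    Returns NaN where either SNP is monomorphic among the co-called.
    """
    vx = ~np.isnan(x)
    vB = ~np.isnan(block)
    valid = vx[:, None] & vB
    n = valid.sum(axis=0).astype(float)
    xf = np.where(vx, x, 0.0)[:, None] * valid
    Bf = np.where(vB, block, 0.0) * valid
    sx = xf.sum(axis=0)
    sy = Bf.sum(axis=0)
    sxx = (xf**2).sum(axis=0)
    syy = (Bf**2).sum(axis=0)
    sxy = (xf * Bf).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx_ = sxx - sx**2 / n
        vy_ = syy - sy**2 / n
        r2 = cov**2 / (vx_ * vy_)
    r2[(n < 2) | (vx_ <= 0) | (vy_ <= 0)] = np.nan
    return r2


def ld_decay(
    panel: GenotypePanel,
    breed: str | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Distance-binned mean r^2 for all same-chromosome SNP pairs of a breed.

    ``breed=None`` uses all samples.  Pairs with distance < ``max_dist`` are
    assigned to half-open bins [k*bin_width, (k+1)*bin_width); monomorphic
    pairs are skipped; empty bins are reported with count 0 and NaN mean.
    Returns columns lo, hi, n_pairs, mean_r2, mean_dist.
    """
    if max_dist % bin_width != 0:
        raise ValueError("max_dist must be a multiple of bin_width")
    if breed is None:
        rows = np.arange(panel.n_samples)
    else:
        idx = panel.breed_indices()
        if breed not in idx:
            raise ValueError(f"unknown breed {breed!r}")
        rows = idx[breed]
    dos = panel.dosages[rows, :].astype(float)
    dos[dos == MISSING] = np.nan

    n_bins = max_dist // bin_width
    sum_r2 = np.zeros(n_bins)
    sum_d = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)

    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    for name in panel.layout.lengths:
        cols = np.where(chrom == name)[0]
        if cols.size < 2:
            continue
        cpos = pos[cols]
        sub = dos[:, cols]
        for i in range(cols.size - 1):
            j_hi = int(np.searchsorted(cpos, cpos[i] + max_dist, side="left"))
            if j_hi <= i + 1:
                continue
            r2 = _pairwise_r2_block(sub[:, i], sub[:, i + 1 : j_hi])
            d = cpos[i + 1 : j_hi] - cpos[i]
            ok = ~np.isnan(r2) & (d > 0)
            if not ok.any():
                continue
            b = d[ok] // bin_width
            np.add.at(sum_r2, b, r2[ok])
            np.add.at(sum_d, b, d[ok])
            np.add.at(count, b, 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(count > 0, sum_r2 / np.maximum(count, 1), np.nan)
        mean_d = np.where(count > 0, sum_d / np.maximum(count, 1), np.nan)
    return pd.DataFrame(
        {
            "lo": np.arange(n_bins) * bin_width,
            "hi": (np.arange(n_bins) + 1) * bin_width,
            "n_pairs": count,
            "mean_r2": mean_r2,
            "mean_dist": mean_d,
        }
    )


def expected_r2(ne: float, c: float, n_samples: int,
                config: LdNeConfig = LdNeConfig()) -> float:
    """Forward Sved map: E[r^2] = 1/(alpha + 4 Ne c) + 1/n."""
    adj = 1.0 / n_samples if config.sample_size_adjust else 0.0
    return 1.0 / (config.alpha + 4.0 * ne * c) + adj


def ne_from_ld(
    bins: pd.DataFrame,
    n_samples: int,
    config: LdNeConfig = LdNeConfig(),
) -> pd.DataFrame:
    """Per-bin effective population size t = 1/(2c) generations ago.

    Bins with zero pairs are skipped; bins whose adjusted r^2 yields a
    non-positive Ne are kept with ``defined = False`` and NaN Ne.  Returns
    columns t, ne, c, r2_adj, lo, hi, n_pairs, defined, sorted by t.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rows = []
    for row in bins.itertuples(index=False):
        if row.n_pairs == 0 or np.isnan(row.mean_r2):
            continue
        c = row.mean_dist * config.morgans_per_bp
        adj = 1.0 / n_samples if config.sample_size_adjust else 0.0
        r2_adj = row.mean_r2 - adj
        t = int(round(1.0 / (2.0 * c)))
        if r2_adj > 0:
            ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - config.alpha)
        else:
            ne = np.nan
        defined = bool(np.isfinite(ne) and ne > 0)
        rows.append(
            {
                "t": t,
                "ne": ne if defined else np.nan,
                "c": c,
                "r2_adj": r2_adj,
                "lo": row.lo,
                "hi": row.hi,
                "n_pairs": row.n_pairs,
                "defined": defined,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["t", "ne", "c", "r2_adj", "lo", "hi", "n_pairs", "defined"],
    )
    return out.sort_values("t", kind="mergesort").reset_index(drop=True)
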