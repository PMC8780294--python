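"""Sliding-window F_ST selection-signature scan.

The scan slides windows of width ``w`` (default 350 kb) with step ``s``
(default 100 kb) along every sequence, averages per-SNP Hudson F_ST within
each window for a contrast, and calls outlier windows by a top-k rank rule
equivalent to a genome-wide percentile threshold.  Called windows are expanded
by 200 kb on each side (a hedge against assembly misplacement) and merged into
maximal disjoint regions.

Contrasts come in three kinds:

* **M1** — one breed against all remaining samples pooled as one population;
* **M2** — the unweighted mean, per window, of the focal breed's pairwise
  window F_ST against each other breed separately;
* **group** — a pooled set of breeds against a pooled reference set (or
  against all remaining breeds).

Windows with fewer than three SNPs are never scored.  Percentile thresholds
are implemented as top-k with ``k = ceil(W * (1 - percentile/100))`` over the
W retained windows, ties broken by genomic order, so that an exact per-breed
window count is reproduced (e.g. 14 of 7,000 windows at the 99.8th
percentile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenomeLayout, GenotypePanel
from .popgen_stats import hudson_fst_panel

__all__ = [
    "ContrastSpec",
    "WindowGrid",
    "RegionCall",
    "choose_window_size",
    "build_windows",
    "scan_contrast",
    "call_outlier_regions",
    "merge_regions",
    "overlap_method_regions",
    "single_marker_outliers",
]

DEFAULT_WINDOW = 350_000
DEFAULT_STEP = 100_000
DEFAULT_MIN_SNPS = 3
DEFAULT_EXPAND = 200_000


@dataclass(frozen=True)
class ContrastSpec:
    """One contrast: kind 'M1'/'M2' with a single focal breed, or 'group'."""

    kind: str
    focal: frozenset[str]
    reference: frozenset[str] | None = None
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("M1", "M2", "group"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.kind in ("M1", "M2") and len(self.focal) != 1:
            raise ValueError(f"{self.kind} contrast requires a single focal breed")
        if self.reference is not None and self.focal & self.reference:
            raise ValueError("focal and reference sets must be disjoint")
        if not self.name:
            label = "+".join(sorted(self.focal))
            object.__setattr__(self, "name", f"{self.kind}:{label}")


@dataclass
class WindowGrid:
    """Sliding windows (0-based half-open) with per-window SNP index ranges.

    ``table`` columns: chrom, start, end, lo, hi, n_snps — where [lo, hi) is
    the contiguous global variant-index range inside the window (variants are
    sorted by sequence then position, so window membership is a slice).
    """

    table: pd.DataFrame
    width: int
    step: int
    min_snps: int

    @property
    def n_windows(self) -> int:
        return len(self.table)


def _windows_for_length(length: int, w: int, s: int) -> list[tuple[int, int]]:
    """Window (start, end) pairs for one sequence, 0-based half-open."""
    if length <= w:
        return [(0, length)]
    starts = list(range(0, length - w + 1, s))
    wins = [(a, a + w) for a in starts]
    if starts[-1] + w < length:  # terminal partial window over uncovered bases
        wins.append((starts[-1] + s, length))
    return wins


def build_windows(
    layout: GenomeLayout,
    variants: pd.DataFrame,
    w: int = DEFAULT_WINDOW,
    s: int = DEFAULT_STEP,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> WindowGrid:
    """Build the sliding-window grid and drop windows with < ``min_snps`` SNPs.

    A SNP at 1-based position ``pos`` belongs to every window whose half-open
    span contains ``pos - 1``; with w/s = 3.5 that is 3-4 windows.
    """
    if w < s:
        raise ValueError("window width must be >= step")
    rows = []
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    offset = 0
    for name, length in layout.lengths.items():
        mask = chrom_arr == name
        cpos = pos_arr[mask] - 1  # 0-based
        n_here = int(mask.sum())
        base = offset
        offset += n_here
        if n_here == 0:
            continue
        for a, b in _windows_for_length(length, w, s):
            lo = base + int(np.searchsorted(cpos, a, side="left"))
            hi = base + int(np.searchsorted(cpos, b, side="left"))
            n = hi - lo
            if n >= min_snps:
                rows.append((name, a, b, lo, hi, n))
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "lo", "hi", "n_snps"]
    )
    return WindowGrid(table=table, width=w, step=s, min_snps=min_snps)


def stabilization_choice(
    sizes: list[int], counts: list[int], tol: float = 0.05
) -> tuple[int, bool]:
    """Smallest size whose successor's sparse-window count dropped by < ``tol``.

    Returns (chosen size, stabilized flag); the largest candidate with a False
    flag when the counts keep dropping through the end of the list.
    """
    for i in range(len(sizes) - 1):
        if counts[i + 1] >= (1 - tol) * counts[i]:
            return sizes[i], True
    return sizes[-1], False


def choose_window_size(
    panel: GenotypePanel,
    candidate_sizes: list[int] | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
    tol: float = 0.05,
) -> tuple[int, pd.DataFrame, bool]:
    """Pick the window size at which the count of sparse windows stabilizes.

    For each candidate size (step = size/3.5 rounded to the nearest kb) the
    number of windows containing fewer than ``min_snps`` SNPs is counted; the
    choice is then :func:`stabilization_choice` over the count table.
    """
    if candidate_sizes is None:
        candidate_sizes = list(range(50_000, 500_001, 50_000))
    if sorted(candidate_sizes) != list(candidate_sizes):
        raise ValueError("candidate sizes must be increasing")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    counts = []
    for size in candidate_sizes:
        step = max(int(round(size / 3.5 / 1000.0)) * 1000, 1000)
        grid = build_windows(panel.layout, panel.variants, size, step, min_snps=0)
        counts.append(int((grid.table["n_snps"] < min_snps).sum()))
    table = pd.DataFrame({"size": candidate_sizes, "n_sparse_windows": counts})
    chosen, stabilized = stabilization_choice(candidate_sizes, counts, tol)
    return chosen, table, stabilized


# ---------------------------------------------------------------------------
# window scoring

def _window_nanmeans(
    values: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and count of non-NaN values over [lo, hi) slices, via cumsums."""
    filled = np.where(np.isnan(values), 0.0, values)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    ccnt = np.concatenate(([0], np.cumsum(~np.isnan(values))))
    n = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    return mean, n


def scan_contrast(
    panel: GenotypePanel,
    grid: WindowGrid,
    contrast: ContrastSpec,
    min_valid_snps: int = DEFAULT_MIN_SNPS,
) -> pd.DataFrame:
    """Per-window mean F_ST for one contrast.

    Returns the grid table with added columns ``fst`` (NaN where the window is
    invalid under this contrast) and ``n_valid`` (valid per-SNP values for
    M1/group; valid pairwise window means for M2).  For M2, each pairwise
    window mean requires ``min_valid_snps`` defined per-SNP values, and the M2
    score averages the pairs whose window mean is defined.
    """
    idx = panel.breed_indices()
    breeds = panel.breeds
    for b in contrast.focal | (contrast.reference or frozenset()):
        if b not in idx:
            raise ValueError(f"contrast {contrast.name!r}: unknown breed {b!r}")
    lo = grid.table["lo"].to_numpy()
    hi = grid.table["hi"].to_numpy()
    out = grid.table.copy()
    out.insert(0, "contrast", contrast.name)

    if contrast.kind == "M2":
        (focal,) = contrast.focal
        others = [b for b in breeds if b != focal]
        pair_means = np.full((len(others), len(lo)), np.nan)
        for k, b in enumerate(others):
            fst = hudson_fst_panel(panel, idx[focal], idx[b])["fst"].to_numpy()
            mean, n = _window_nanmeans(fst, lo, hi)
            pair_means[k] = np.where(n >= min_valid_snps, mean, np.nan)
        n_valid = (~np.isnan(pair_means)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            score = np.nanmean(
                np.where(np.isnan(pair_means), np.nan, pair_means), axis=0
            )
        out["fst"] = np.where(n_valid > 0, score, np.nan)
        out["n_valid"] = n_valid
        return out

    if contrast.kind == "M1":
        (focal,) = contrast.focal
        rows1 = idx[focal]
        rows2 = np.concatenate([idx[b] for b in breeds if b != focal])
    else:  # group
        rows1 = np.concatenate([idx[b] for b in sorted(contrast.focal)])
        ref = (
            sorted(contrast.reference)
            if contrast.reference is not None
            else [b for b in breeds if b not in contrast.focal]
        )
        if not ref:
            raise ValueError(f"contrast {contrast.name!r}: empty reference side")
        rows2 = np.concatenate([idx[b] for b in ref])
    fst = hudson_fst_panel(panel, rows1, rows2)["fst"].to_numpy()
    mean, n = _window_nanmeans(fst, lo, hi)
    out["fst"] = np.where(n >= min_valid_snps, mean, np.nan)
    out["n_valid"] = n
    return out


# ---------------------------------------------------------------------------
# region calling

@dataclass
class RegionCall:
    """A merged, expanded outlier interval (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    contrasts: set[str] = field(default_factory=set)
    methods: set[str] = field(default_factory=set)
    percentile: float = 0.0
    windows: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def top_k_count(n_retained: int, percentile: float) -> int:
    """k = ceil(W * (1 - percentile/100)) — the top-k rank form of a percentile.

    ``percentile == 100`` yields k = 0 (no windows called).
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    # small epsilon guards against float fuzz (7000 * 0.002 must give k = 14)
    return math.ceil(n_retained * (100.0 - percentile) / 100.0 - 1e-9)


def call_outlier_regions(
    scores: pd.DataFrame,
    percentile: float,
    layout: GenomeLayout,
    expand_bp: int = DEFAULT_EXPAND,
) -> list[RegionCall]:
    """Call outlier regions from one contrast's window scores.

    The top k = ceil(W * (1 - percentile/100)) valid windows by mean F_ST
    (ties broken by genomic order) are each expanded by ``expand_bp`` on both
    sides, clamped to the sequence, and merged — treating abutting intervals
    as overlapping — into maximal disjoint regions reported 1-based inclusive.
    """
    valid = scores[~scores["fst"].isna()]
    if len(valid) == 0:
        raise ValueError("no valid window scores to threshold")
    k = top_k_count(len(valid), percentile)
    if k == 0:
        return []
    order = layout.order_index()
    ranked = valid.assign(_c=valid["chrom"].map(order)).sort_values(
        ["fst", "_c", "start"], ascending=[False, True, True], kind="mergesort"
    )
    top = ranked.head(k)
    method = str(scores["contrast"].iloc[0]).split(":", 1)[0]
    intervals = []
    for row in top.itertuples(index=False):
        L = layout.lengths[row.chrom]
        a = max(0, row.start - expand_bp)
        b = min(L, row.end + expand_bp)
        intervals.append(
            RegionCall(
                chrom=row.chrom,
                start=a + 1,
                end=b,
                contrasts={row.contrast},
                methods={method},
                percentile=percentile,
                windows=[(row.start + 1, row.end, float(row.fst))],
            )
        )
    return merge_regions(intervals, layout)


def merge_regions(
    regions: list[RegionCall], layout: GenomeLayout
) -> list[RegionCall]:
    """Merge overlapping or abutting regions into maximal disjoint regions.

    Provenance (contrast names, methods, member windows) is unioned; the
    percentile carried is the least stringent among members.
    """
    order = layout.order_index()
    merged: list[RegionCall] = []
    for reg in sorted(regions, key=lambda r: (order[r.chrom], r.start, r.end)):
        if (
            merged
            and merged[-1].chrom == reg.chrom
            and reg.start <= merged[-1].end + 1  # abutting counts as overlap
        ):
            last = merged[-1]
            last.end = max(last.end, reg.end)
            last.contrasts |= reg.contrasts
            last.methods |= reg.methods
            last.windows.extend(reg.windows)
            last.percentile = min(last.percentile, reg.percentile) or reg.percentile
        else:
            merged.append(
                RegionCall(
                    chrom=reg.chrom,
                    start=reg.start,
                    end=reg.end,
                    contrasts=set(reg.contrasts),
                    methods=set(reg.methods),
                    percentile=reg.percentile,
                    windows=list(reg.windows),
                )
            )
    return merged


def overlap_method_regions(
    m1: list[RegionCall], m2: list[RegionCall], layout: GenomeLayout
) -> tuple[list[RegionCall], list[RegionCall]]:
    """Union and method-overlap of two region call sets.

    The union merges all regions across both sets into maximal disjoint
    regions; the overlap set keeps union regions supported by at least one
    region from each method (per the ``methods`` provenance).
    """
    union = merge_regions(list(m1) + list(m2), layout)
    methods_needed = set()
    for r in list(m1) + list(m2):
        methods_needed |= r.methods
    if len(methods_needed) < 2:
        overlap = []
    else:
        overlap = [r for r in union if len(r.methods) >= 2]
    return overlap, union


def regions_to_frame(regions: list[RegionCall]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "contrasts": ";".join(sorted(r.contrasts)),
            "methods": ";".join(sorted(r.methods)),
            "percentile": r.percentile,
            "n_windows": len(r.windows),
            "max_window_fst": max((w[2] for w in r.windows), default=np.nan),
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length", "contrasts", "methods",
            "percentile", "n_windows", "max_window_fst",
        ],
    )


def regions_to_bed(regions: list[RegionCall]) -> pd.DataFrame:
    """0-based half-open BED representation of a region list."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "name": [";".join(sorted(r.contrasts)) for r in regions],
        }
    )


def single_marker_outliers(
    snp_fst: pd.DataFrame, percentile: float = 99.95
) -> pd.DataFrame:
    """Top-k single SNPs by F_ST: k = ceil(L_valid * (1 - percentile/100)).

    ``snp_fst`` needs columns id, chrom, pos, fst.  Ties are broken by genomic
    order; the result is sorted by decreasing F_ST.
    """
    valid = snp_fst[~snp_fst["fst"].isna()].reset_index(drop=True)
    k = top_k_count(len(valid), percentile)
    ranked = valid.assign(_row=np.arange(len(valid))).sort_values(
        ["fst", "_row"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(k).drop(columns="_row").reset_index(drop=True)
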