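"""Gene annotation of called regions and Fisher's-exact over-representation.

Regions are intersected with protein-coding gene records from a GFF3 file: a
gene is assigned to a region iff their 1-based inclusive intervals overlap by
at least one base (regions were already expanded upstream, so no extra
promoter flank is added here).  Over-representation of the resulting gene set
against user-supplied GMT libraries uses the one-sided Fisher's exact
(hypergeometric upper-tail) test with Benjamini-Hochberg adjustment, and the
reporting rule that an enriched term must contain at least two input genes
drawn from at least two distinct regions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sweep_scan import RegionCall

__all__ = [
    "GeneRecord",
    "read_gff_genes",
    "read_gmt",
    "intersect_genes",
    "ora_fisher",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene: symbol, sequence, 1-based inclusive span, biotype."""

    symbol: str
    chrom: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start > end")


def read_gff_genes(
    path: str | os.PathLike, protein_coding_only: bool = True
) -> list[GeneRecord]:
    """Read ``gene`` features from a GFF3 file.

    The gene symbol is taken from the ``Name`` attribute (falling back to
    ``gene`` then ``ID``); the biotype from ``gene_biotype``/``biotype``
    (defaulting to protein_coding when absent).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        symbol = (attrs.get("Name") or attrs.get("gene") or attrs.get("ID"))[0]
        biotype = (attrs.get("gene_biotype") or attrs.get("biotype")
                   or ["protein_coding"])[0]
        if protein_coding_only and biotype != "protein_coding":
            continue
        genes.append(
            GeneRecord(
                symbol=symbol, chrom=feat.seqid, start=feat.start, end=feat.end,
                biotype=biotype,
            )
        )
    return genes


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT gene-set library: term<TAB>description<TAB>gene..."""
    library: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            library[parts[0]] = {g for g in parts[2:] if g}
    return library


def intersect_genes(
    regions: list[RegionCall], genes: list[GeneRecord]
) -> pd.DataFrame:
    """Assign genes to regions by >= 1 bp overlap (1-based inclusive intervals).

    Unplaced scaffolds are handled identically to chromosomes.  Raises when a
    region names a sequence carrying no gene record and vice versa is fine —
    the error is only for sequence-name mismatch between both inputs being
    empty; unknown region sequences simply yield no genes.  Returns one row
    per (region, gene) with columns region_chrom, region_start, region_end,
    gene, gene_start, gene_end.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open key: [start, end + 1) so 1-bp overlap is interval overlap
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    rows = []
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(r.start, r.end + 1)):
            g = hit.data
            rows.append(
                (r.chrom, r.start, r.end, g.symbol, g.start, g.end, g.biotype)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_chrom", "region_start", "region_end",
            "gene", "gene_start", "gene_end", "biotype",
        ],
    )


def ora_fisher(
    input_genes: set[str],
    background: set[str],
    library: dict[str, set[str]],
    gene_regions: dict[str, set[tuple[str, int, int]]] | None = None,
    min_support_windows: int = 2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided Fisher's exact over-representation with BH adjustment.

    Per term (intersected with the background): the hypergeometric upper tail
    P(X >= overlap | N, K, n).  Returns ``(filtered, full)`` tables; the
    filtered table keeps terms with overlap >= 2 genes, adjusted p < alpha,
    and — when ``gene_regions`` maps genes to their supporting regions — with
    overlap genes drawn from >= ``min_support_windows`` distinct regions.
    """
    if not input_genes or not background:
        raise ValueError("input and background gene sets must be non-empty")
    if not input_genes <= background:
        raise ValueError("input genes must be a subset of the background")
    N = len(background)
    n = len(input_genes)
    rows = []
    for term, members in library.items():
        members = members & background
        if not members:
            continue
        overlap = members & input_genes
        K = len(members)
        x = len(overlap)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        n_regions = 0
        if gene_regions is not None:
            regions = set()
            for g in overlap:
                regions |= gene_regions.get(g, set())
            n_regions = len(regions)
        rows.append(
            {
                "term": term,
                "term_size": K,
                "overlap": x,
                "overlap_genes": ";".join(sorted(overlap)),
                "n_regions": n_regions,
                "p": p,
            }
        )
    full = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "overlap_genes",
                       "n_regions", "p"]
    )
    if len(full):
        full["p_adj"] = multipletests(full["p"].to_numpy(), method="fdr_bh")[1]
        full = full.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        full["p_adj"] = pd.Series(dtype=float)
    keep = (full["overlap"] >= 2) & (full["p_adj"] < alpha)
    if gene_regions is not None:
        keep &= full["n_regions"] >= min_support_windows
    return full[keep].reset_index(drop=True), full
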