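"""Per-breed diversity statistics and per-SNP Hudson F_ST.

The Hudson estimator for a biallelic SNP with allele frequencies p1, p2
estimated from n1, n2 sampled alleles is the ratio N/D with

    N = (p1 - p2)^2 - p1(1-p1)/(n1 - 1) - p2(1-p2)/(n2 - 1)
    D = p1(1-p2) + p2(1-p1)

It is nearly unbiased and insensitive to unequal sample sizes, which is why it
is the estimator of choice when breeds of 6 to 256 animals are contrasted.
Values can be negative (they are not truncated); a value is undefined when
D = 0 (SNP monomorphic across both sides) or when either side has fewer than
4 called alleles (the n-1 correction needs at least two genotypes).

Genome-wide and per-window F_ST are unweighted means of per-SNP ratios
("average of ratios"); a ratio-of-sums alternative is available via
``ratio_of_averages=True`` on the mean helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

__all__ = [
    "allele_stats",
    "fis",
    "breed_summaries",
    "hudson_fst_per_snp",
    "hudson_fst_panel",
    "fst_mean",
    "fst_matrix",
    "pairwise_fst_store",
    "region_observed_heterozygosity",
]

MIN_ALLELES = 4  # fewer called alleles than this on a side -> undefined value


def allele_stats(
    dosages: np.ndarray, rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ALT-allele frequency and called-allele count for a sample set.

    Returns ``(p, n)`` where ``n = 2 x called genotypes`` (even) and ``p`` is
    NaN where ``n == 0``.
    """
    sub = dosages if rows is None else dosages[rows, :]
    called = sub != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n.astype(np.int64)


def fis(ho: float, he: float) -> float:
    """Within-population inbreeding coefficient, F_IS = 1 - Ho/He."""
    if he == 0:
        raise ValueError("F_IS undefined when expected heterozygosity is 0")
    return 1.0 - ho / he


def _breed_snp_stats(
    dosages: np.ndarray, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (Ho, He, MAF) among called genotypes of one breed; NaN where
    the breed has no calls at the SNP."""
    sub = dosages[rows, :]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    het = ((sub == 1) & called).sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
        p = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
    he = 2 * p * (1 - p)
    maf = np.minimum(p, 1 - p)
    return ho, he, maf


def breed_summaries(panel: GenotypePanel) -> pd.DataFrame:
    """Per-breed mean MAF/Ho/He (with sd) and the breed-level F_IS.

    Per SNP within a breed: Ho is the heterozygote fraction among called
    genotypes; He = 2p(1-p) from the called allele frequency; MAF = min(p,
    1-p).  Breed-level values are unweighted means over SNPs with at least one
    called genotype; F_IS = 1 - mean(Ho)/mean(He) is one number per breed.
    Also counts SNPs with MAF < 0.05 (strict) and MAF >= 0.45 (inclusive).
    """
    rows_out = []
    for breed, rows in panel.breed_indices().items():
        if len(rows) < 2:
            raise ValueError(f"breed {breed!r} has fewer than 2 samples")
        ho, he, maf = _breed_snp_stats(panel.dosages, rows)
        valid = ~np.isnan(ho)
        if not valid.any():
            raise ValueError(f"breed {breed!r} has zero called genotypes at all SNPs")
        mean_he = float(np.nanmean(he))
        mean_ho = float(np.nanmean(ho))
        rows_out.append(
            {
                "breed": breed,
                "n_samples": len(rows),
                "maf_mean": float(np.nanmean(maf)),
                "maf_sd": float(np.nanstd(maf)),
                "ho_mean": mean_ho,
                "ho_sd": float(np.nanstd(ho)),
                "he_mean": mean_he,
                "he_sd": float(np.nanstd(he)),
                "fis": fis(mean_ho, mean_he),
                "n_maf_lt_005": int(np.nansum(maf < 0.05)),
                "n_maf_ge_045": int(np.nansum(maf >= 0.45)),
            }
        )
    return pd.DataFrame(rows_out)


def hudson_fst_per_snp(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> pd.DataFrame:
    """Per-SNP Hudson numerator, denominator and ratio for one contrast.

    Inputs are per-SNP allele frequencies and called-allele counts for the two
    sides.  The value is NaN where D = 0 or either side has < 4 called
    alleles; negative values are kept.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= MIN_ALLELES) & (n2 >= MIN_ALLELES)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1e-300)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1e-300)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        value = np.where(ok & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return pd.DataFrame({"num": num, "den": den, "fst": value})


def hudson_fst_panel(
    panel: GenotypePanel,
    rows1: np.ndarray,
    rows2: np.ndarray,
) -> pd.DataFrame:
    """Hudson F_ST per SNP between two disjoint sample-index sets of a panel."""
    p1, n1 = allele_stats(panel.dosages, rows1)
    p2, n2 = allele_stats(panel.dosages, rows2)
    out = hudson_fst_per_snp(p1, n1, p2, n2)
    out.insert(0, "id", panel.variants["id"].to_numpy())
    return out


def fst_mean(fst_values: np.ndarray, ratio_of_averages: bool = False,
             num: np.ndarray | None = None, den: np.ndarray | None = None) -> float:
    """Mean F_ST over SNPs with a defined value.

    Default is the unweighted mean of per-SNP ratios; with
    ``ratio_of_averages=True`` (requires ``num``/``den``) the Bhatia-style
    sum(N)/sum(D) is returned instead.
    """
    if ratio_of_averages:
        if num is None or den is None:
            raise ValueError("ratio_of_averages requires num and den arrays")
        ok = ~np.isnan(num) & ~np.isnan(den)
        d = np.nansum(den[ok])
        if d == 0:
            raise ValueError("zero total denominator")
        return float(np.nansum(num[ok]) / d)
    vals = fst_values[~np.isnan(fst_values)]
    if vals.size == 0:
        raise ValueError("no SNPs with a defined F_ST value")
    return float(vals.mean())


def pairwise_fst_store(panel: GenotypePanel) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-SNP Hudson tables for every unordered breed pair.

    Keys are (breed_i, breed_j) with i < j in panel breed order.
    """
    breeds = panel.breeds
    idx = panel.breed_indices()
    stats = {b: allele_stats(panel.dosages, idx[b]) for b in breeds}
    store: dict[tuple[str, str], pd.DataFrame] = {}
    for i, bi in enumerate(breeds):
        for bj in breeds[i + 1 :]:
            p1, n1 = stats[bi]
            p2, n2 = stats[bj]
            store[(bi, bj)] = hudson_fst_per_snp(p1, n1, p2, n2)
    return store


def fst_matrix(
    panel: GenotypePanel,
    store: dict[tuple[str, str], pd.DataFrame] | None = None,
    ratio_of_averages: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Breed x breed matrix of mean per-SNP Hudson F_ST, plus the per-pair store.

    By default entry (i, j) is the unweighted mean over SNPs with a defined
    value for that pair; ``ratio_of_averages=True`` switches to the
    Bhatia-style sum(N)/sum(D), which is the unbiased estimator of the drift
    F under the island model (the per-SNP-ratio average is shrunk toward 0 —
    see the methods note).  The matrix is symmetric with a zero diagonal.
    """
    breeds = panel.breeds
    if len(breeds) < 2:
        raise ValueError("need at least 2 breeds")
    if store is None:
        store = pairwise_fst_store(panel)
    mat = pd.DataFrame(0.0, index=breeds, columns=breeds)
    for (bi, bj), tab in store.items():
        vals = tab["fst"].to_numpy()
        if np.isnan(vals).all():
            raise ValueError(f"pair ({bi}, {bj}) has zero SNPs with a defined F_ST")
        m = fst_mean(
            vals,
            ratio_of_averages=ratio_of_averages,
            num=tab["num"].to_numpy(),
            den=tab["den"].to_numpy(),
        )
        mat.loc[bi, bj] = m
        mat.loc[bj, bi] = m
    return mat, store


def region_observed_heterozygosity(
    panel: GenotypePanel,
    chrom: str,
    start: int,
    end: int,
    breed: str,
) -> tuple[pd.DataFrame, float]:
    """Per-SNP Ho for one breed over a closed 1-based interval, plus the mean.

    The region-level mean is unweighted over the SNPs in the interval that
    have at least one called genotype in the breed.
    """
    if chrom not in panel.layout:
        raise ValueError(f"unknown sequence {chrom!r}")
    idx = panel.breed_indices()
    if breed not in idx:
        raise ValueError(f"unknown breed {breed!r}")
    v = panel.variants
    mask = (v["chrom"] == chrom) & (v["pos"] >= start) & (v["pos"] <= end)
    cols = np.where(mask.to_numpy())[0]
    if cols.size == 0:
        raise ValueError(f"no SNPs in {chrom}:{start}-{end}")
    sub = panel.dosages[np.ix_(idx[breed], cols)]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, ((sub == 1) & called).sum(axis=0)
                      / np.maximum(n_called, 1), np.nan)
    tab = pd.DataFrame(
        {
            "id": v.loc[mask, "id"].to_numpy(),
            "pos": v.loc[mask, "pos"].to_numpy(),
            "ho": ho,
            "n_called": n_called,
        }
    )
    return tab, float(np.nanmean(ho))
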