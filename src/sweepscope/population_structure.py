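"""Breed relationships: neighbour-joining tree with bootstrap, and MDS.

The NJ tree is built (Saitou-Nei agglomeration, delegated to scikit-bio) from
the breed x breed matrix of mean per-SNP Hudson F_ST.  Bootstrap support
resamples SNP columns with replacement — the distance is a per-SNP average, so
SNPs are the natural resampling unit — rebuilds the matrix from the per-pair
per-SNP F_ST store, rebuilds the tree and scores bipartitions.

Individual-level structure is summarized by classical (Torgerson)
multidimensional scaling of the 1 - IBS distance matrix, where IBS similarity
between two samples is the mean over co-called SNPs of (2 - |d_i - d_j|) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .genotype_io import MISSING, GenotypePanel

__all__ = [
    "BreedTree",
    "MdsEmbedding",
    "nj_tree",
    "ibs_distance_matrix",
    "classical_mds",
    "mds_embed",
]


@dataclass
class BreedTree:
    """Unrooted NJ tree over breeds with bootstrap supports per bipartition."""

    tree: TreeNode
    supports: dict[frozenset[str], float]  # leaf subset (normalized) -> % support
    n_boot: int

    def newick(self) -> str:
        """Newick string with supports as internal-node labels."""
        annotated = self.tree.copy()
        taxa = frozenset(t.name for t in annotated.tips())
        anchor = min(taxa)
        for node in annotated.non_tips():
            subset = frozenset(t.name for t in node.tips())
            key = _normalize_bipartition(subset, taxa, anchor)
            if key in self.supports:
                node.name = f"{self.supports[key]:.0f}"
        return str(annotated).strip()


def _normalize_bipartition(
    subset: frozenset[str], taxa: frozenset[str], anchor: str
) -> frozenset[str]:
    """Represent an unrooted bipartition by the side not containing the anchor."""
    return taxa - subset if anchor in subset else subset


def _bipartitions(tree: TreeNode, taxa: frozenset[str], anchor: str
                  ) -> set[frozenset[str]]:
    parts = set()
    for node in tree.non_tips():
        subset = frozenset(t.name for t in node.tips())
        if 1 < len(subset) < len(taxa) - 1:
            parts.add(_normalize_bipartition(subset, taxa, anchor))
    return parts


def _nj_from_matrix(mat: pd.DataFrame) -> TreeNode:
    dm = DistanceMatrix(mat.to_numpy(), ids=list(mat.index))
    return nj(dm, neg_as_zero=True)


def nj_tree(
    fst: pd.DataFrame,
    snp_fst_store: dict[tuple[str, str], pd.DataFrame] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> BreedTree:
    """Neighbour-joining tree from an F_ST matrix, with SNP-bootstrap supports.

    ``fst`` must be a symmetric DataFrame with zero diagonal and >= 3 breeds.
    When ``snp_fst_store`` (per-pair per-SNP Hudson tables, as produced by
    :func:`sweepscope.popgen_stats.pairwise_fst_store`) is given and
    ``n_boot > 0``, SNP columns are resampled with replacement, the mean-F_ST
    matrix and tree are rebuilt per replicate, and each internal bipartition
    of the point-estimate tree is scored by the percentage of replicates
    containing it.  Deterministic given ``seed``.
    """
    breeds = list(fst.index)
    if len(breeds) < 3:
        raise ValueError("need at least 3 breeds for a tree")
    arr = fst.to_numpy()
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("F_ST matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("F_ST matrix must have a zero diagonal")

    tree = _nj_from_matrix(fst)
    taxa = frozenset(breeds)
    anchor = min(taxa)
    ref_parts = _bipartitions(tree, taxa, anchor)
    supports = {part: 0.0 for part in ref_parts}

    if snp_fst_store and n_boot > 0:
        pair_vals = {k: v["fst"].to_numpy() for k, v in snp_fst_store.items()}
        L = len(next(iter(pair_vals.values())))
        rng = np.random.default_rng(seed)
        hits = {part: 0 for part in ref_parts}
        for _ in range(n_boot):
            cols = rng.integers(0, L, size=L)
            boot = pd.DataFrame(0.0, index=breeds, columns=breeds)
            for (bi, bj), vals in pair_vals.items():
                v = vals[cols]
                m = float(np.nanmean(v))
                boot.loc[bi, bj] = m
                boot.loc[bj, bi] = m
            boot_parts = _bipartitions(_nj_from_matrix(boot), taxa, anchor)
            for part in ref_parts & boot_parts:
                hits[part] += 1
        supports = {p: 100.0 * h / n_boot for p, h in hits.items()}
    return BreedTree(tree=tree, supports=supports, n_boot=n_boot)


# ---------------------------------------------------------------------------
# MDS

@dataclass
class MdsEmbedding:
    coords: pd.DataFrame       # samples x d, columns C1..Cd
    eigenvalues: np.ndarray    # all eigenvalues, decreasing


def ibs_distance_matrix(panel: GenotypePanel) -> pd.DataFrame:
    """Pairwise 1 - IBS distances over co-called SNPs, for all samples.

    Computed from genotype-class indicator matrices so the whole n x n matrix
    is a handful of matrix products.
    """
    d = panel.dosages
    called = (d != MISSING).astype(np.float64)
    ind = [(d == g).astype(np.float64) for g in (0, 1, 2)]
    n_co = called @ called.T
    if (n_co == 0).any():
        i, j = np.argwhere(n_co == 0)[0]
        raise ValueError(
            f"samples {panel.samples[i]!r} and {panel.samples[j]!r} share no "
            "co-called SNPs"
        )
    # sum over pairs of |g - h| weights: |0-1|=|1-2|=1, |0-2|=2
    absdiff = (
        ind[0] @ ind[1].T + ind[1] @ ind[0].T
        + ind[1] @ ind[2].T + ind[2] @ ind[1].T
        + 2 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T)
    )
    sim = (2 * n_co - absdiff) / (2 * n_co)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=panel.samples, columns=panel.samples)


def classical_mds(dist: np.ndarray, d: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling: eigendecomposition of the double-centered Gram matrix.

    Returns (coords, eigenvalues) with coordinates for the top-``d``
    components ordered by decreasing eigenvalue; components with non-positive
    eigenvalues get zero coordinates.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if d >= n:
        raise ValueError("embedding dimension must be < number of points")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    coords = np.zeros((n, d))
    for k in range(d):
        if evals[k] > 0:
            coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
    return coords, evals


def mds_embed(panel: GenotypePanel, d: int = 3) -> MdsEmbedding:
    """Classical MDS of all samples on the 1 - IBS distance matrix."""
    if panel.n_samples < d + 1:
        raise ValueError("need at least d + 1 samples")
    dist = ibs_distance_matrix(panel).to_numpy()
    coords, evals = classical_mds(dist, d)
    frame = pd.DataFrame(
        coords, index=panel.samples, columns=[f"C{k + 1}" for k in range(d)]
    )
    frame.insert(0, "breed", [panel.breed_of[s] for s in panel.samples])
    return MdsEmbedding(coords=frame, eigenvalues=evals)
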