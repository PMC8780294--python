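import itertools

import numpy as np
import pandas as pd
import pytest

from sweepscope.population_structure import (
    _bipartitions,
    classical_mds,
    ibs_distance_matrix,
    mds_embed,
    nj_tree,
)
from conftest import build_panel


def _additive_distances(ids, cherry_splits, lengths):
    """Distance matrix of a 5-taxon tree given its two cherries and leaf/internal
    branch lengths (dict leaf->len plus ('e1','e2') internal lengths)."""
    # path lengths via explicit tree: ((a,b),(c,d),e) caterpillar-free layout
    (a, b), (c, d) = cherry_splits
    e = [t for t in ids if t not in (a, b, c, d)][0]
    leaf = lengths
    d_ = {}
    def put(x, y, v):
        d_[(x, y)] = v
        d_[(y, x)] = v
    put(a, b, leaf[a] + leaf[b])
    put(c, d, leaf[c] + leaf[d])
    put(a, c, leaf[a] + lengths["e1"] + lengths["e2"] + leaf[c])
    put(a, d, leaf[a] + lengths["e1"] + lengths["e2"] + leaf[d])
    put(b, c, leaf[b] + lengths["e1"] + lengths["e2"] + leaf[c])
    put(b, d, leaf[b] + lengths["e1"] + lengths["e2"] + leaf[d])
    put(a, e, leaf[a] + lengths["e1"] + leaf[e])
    put(b, e, leaf[b] + lengths["e1"] + leaf[e])
    put(c, e, leaf[c] + lengths["e2"] + leaf[e])
    put(d, e, leaf[d] + lengths["e2"] + leaf[e])
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for (x, y), v in d_.items():
        mat.loc[x, y] = v
    return mat


def _four_point_cherries(mat):
    """Independent oracle: the 2-subsets that satisfy the strict four-point
    condition (valid cherry splits of the additive tree)."""
    ids = list(mat.index)
    found = set()
    for i, j in itertools.combinations(ids, 2):
        rest = [t for t in ids if t not in (i, j)]
        ok = True
        for k, l in itertools.combinations(rest, 2):
            s1 = mat.loc[i, j] + mat.loc[k, l]
            s2 = mat.loc[i, k] + mat.loc[j, l]
            s3 = mat.loc[i, l] + mat.loc[j, k]
            if not (abs(s2 - s3) < 1e-9 and s1 < s2 - 1e-9):
                ok = False
                break
        if ok:
            found.add(frozenset((i, j)))
    return found


class TestNjTree:
    def test_three_taxon_closed_form(self):
        mat = pd.DataFrame(
            [[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        bt = nj_tree(mat, n_boot=0)
        lengths = {t.name: t.length for t in bt.tree.tips()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.3)

    def test_recovers_additive_five_taxon_topology(self):
        """On additive distances, NJ must find exactly the cherry splits the
        exhaustive four-point-condition search identifies."""
        ids = list("ABCDE")
        lengths = {"A": 0.05, "B": 0.11, "C": 0.07, "D": 0.16, "E": 0.09,
                   "e1": 0.04, "e2": 0.06}
        mat = _additive_distances(ids, (("A", "B"), ("C", "D")), lengths)
        oracle = _four_point_cherries(mat)
        assert oracle == {frozenset("AB"), frozenset("CD")}
        bt = nj_tree(mat, n_boot=0)
        taxa = frozenset(ids)
        parts = _bipartitions(bt.tree, taxa, min(taxa))
        normalized = {p if len(p) == 2 else taxa - p for p in parts}
        assert normalized == oracle

    def test_invariant_to_taxon_order(self):
        ids = list("ABCDE")
        lengths = {"A": 0.05, "B": 0.11, "C": 0.07, "D": 0.16, "E": 0.09,
                   "e1": 0.04, "e2": 0.06}
        mat = _additive_distances(ids, (("A", "B"), ("C", "D")), lengths)
        perm = ["D", "A", "E", "B", "C"]
        bt1 = nj_tree(mat, n_boot=0)
        bt2 = nj_tree(mat.loc[perm, perm], n_boot=0)
        taxa = frozenset(ids)
        assert _bipartitions(bt1.tree, taxa, "A") == _bipartitions(
            bt2.tree, taxa, "A"
        )

    def test_bootstrap_on_identical_snp_columns_gives_full_support(self):
        ids = list("ABCD")
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        vals = {("A", "B"): 0.1, ("A", "C"): 0.3, ("A", "D"): 0.32,
                ("B", "C"): 0.3, ("B", "D"): 0.32, ("C", "D"): 0.08}
        store = {}
        for (i, j), v in vals.items():
            mat.loc[i, j] = mat.loc[j, i] = v
            store[(i, j)] = pd.DataFrame({"fst": np.full(60, v),
                                          "num": np.full(60, v),
                                          "den": np.ones(60)})
        bt = nj_tree(mat, store, n_boot=50, seed=1)
        assert bt.supports, "expected at least one internal bipartition"
        assert all(s == 100.0 for s in bt.supports.values())
        assert "100" in bt.newick()

    def test_rejects_asymmetric_and_tiny_inputs(self):
        bad = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="3 breeds"):
            nj_tree(bad, n_boot=0)
        mat = pd.DataFrame(
            [[0, 0.3, 0.4], [0.2, 0, 0.5], [0.4, 0.5, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(mat, n_boot=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        ids = list("ABCDE")
        lengths = {"A": 0.05, "B": 0.11, "C": 0.07, "D": 0.16, "E": 0.09,
                   "e1": 0.04, "e2": 0.06}
        mat = _additive_distances(ids, (("A", "B"), ("C", "D")), lengths)
        store = {}
        for i, j in itertools.combinations(ids, 2):
            base = mat.loc[i, j]
            v = base + rng.normal(0, 0.02, 200)
            store[(i, j)] = pd.DataFrame({"fst": v, "num": v, "den": np.ones(200)})
        mean_mat = mat.copy()
        for i, j in itertools.combinations(ids, 2):
            m = float(store[(i, j)]["fst"].mean())
            mean_mat.loc[i, j] = mean_mat.loc[j, i] = m
        a = nj_tree(mean_mat, store, n_boot=30, seed=9)
        b = nj_tree(mean_mat, store, n_boot=30, seed=9)
        assert a.supports == b.supports


class TestClassicalMds:
    def test_planar_points_reproduced_to_1e9(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 1.1], [1.4, 1.5]])
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, evals = classical_mds(dist, d=2)
        redist = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(redist, dist, atol=1e-9)
        assert evals[0] >= evals[1] > 0

    def test_colinear_points_recover_spacings_up_to_sign(self):
        x = np.array([0.0, 1.0, 2.5, 4.0])
        dist = np.abs(x[:, None] - x[None, :])
        coords, _ = classical_mds(dist, d=1)
        spac = np.diff(np.sort(coords[:, 0]))
        expected = np.diff(x)
        assert np.allclose(spac, expected, atol=1e-9) or np.allclose(
            spac, expected[::-1], atol=1e-9
        )

    def test_identical_samples_get_identical_coordinates(self):
        dos = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0], [1, 0, 1, 2]],
                       dtype=np.int8)
        panel = build_panel(dos, breeds=["A", "A", "B", "B"])
        emb = mds_embed(panel, d=2)
        c = emb.coords[["C1", "C2"]].to_numpy()
        assert np.allclose(c[0], c[1], atol=1e-12)


def test_two_cluster_panel_separates_in_tree_and_mds():
    """Two clusters of breeds drawn around independent frequency profiles:
    the NJ tree contains the cluster bipartition and MDS dimension 1
    separates the cluster means."""
    rng = np.random.default_rng(4)
    m = 800
    pA = rng.uniform(0.1, 0.9, m)
    pB = rng.uniform(0.1, 0.9, m)
    breeds, rows = [], []
    cluster = {"A1": pA, "A2": pA, "A3": pA, "B1": pB, "B2": pB, "B3": pB}
    for breed, p in cluster.items():
        q = np.clip(p + rng.normal(0, 0.05, m), 0.01, 0.99)  # low within-cluster F
        for _ in range(15):
            rows.append(rng.binomial(2, q))
            breeds.append(breed)
    dos = np.array(rows, dtype=np.int8)
    panel = build_panel(dos, breeds=breeds,
                        positions=[(j + 1) * 1000 for j in range(m)],
                        seq_lengths={"chr1": 10_000_000})
    from sweepscope.popgen_stats import fst_matrix

    mat, _ = fst_matrix(panel)
    bt = nj_tree(mat, n_boot=0)
    taxa = frozenset(cluster)
    parts = _bipartitions(bt.tree, taxa, min(taxa))
    split = frozenset({"A1", "A2", "A3"})
    normalized = {p if "A1" in p else taxa - p for p in parts}
    assert split in normalized

    emb = mds_embed(panel, d=2)
    c1 = emb.coords.groupby("breed")["C1"].mean()
    a_side = c1[["A1", "A2", "A3"]].to_numpy()
    b_side = c1[["B1", "B2", "B3"]].to_numpy()
    assert (np.sign(a_side) == np.sign(a_side[0])).all()
    assert (np.sign(b_side) == -np.sign(a_side[0])).all()


def test_ibs_distance_zero_cocalled_pair_raises():
    from sweepscope.genotype_io import MISSING

    dos = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
    panel = build_panel(dos, breeds=["A", "B"])
    with pytest.raises(ValueError, match="co-called"):
        ibs_distance_matrix(panel)
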