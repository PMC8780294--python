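import numpy as np
import pandas as pd
import pytest

from sweepscope.genotype_io import GenomeLayout
from sweepscope.popgen_stats import hudson_fst_panel
from sweepscope.sweep_scan import (
    ContrastSpec,
    RegionCall,
    build_windows,
    call_outlier_regions,
    choose_window_size,
    merge_regions,
    overlap_method_regions,
    regions_to_bed,
    scan_contrast,
    single_marker_outliers,
    stabilization_choice,
    top_k_count,
)
from sweepscope.synthetic_data import (
    PlantedSweep,
    SimScenario,
    make_paper_like_scenario,
    simulate_panel,
)
from conftest import build_panel


def _variants(chrom_positions):
    rows = []
    for c, ps in chrom_positions.items():
        for p in ps:
            rows.append((f"{c}_{p}", c, p, "A", "G"))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "a1", "a2"])


class TestBuildWindows:
    def test_one_megabase_grid_arithmetic(self):
        """L = 1 Mb, w = 350 kb, s = 100 kb: exactly 7 full windows starting
        at 0, 100k, ..., 650k (the last covers through the sequence end)."""
        layout = GenomeLayout(lengths={"c": 1_000_000})
        variants = _variants({"c": list(range(5_000, 1_000_000, 5_000))})
        grid = build_windows(layout, variants)
        full = grid.table[grid.table["end"] - grid.table["start"] == 350_000]
        assert len(full) == 7
        assert list(full["start"]) == [i * 100_000 for i in range(7)]
        # a terminal partial window covers the bases the full grid leaves out
        tail = grid.table[grid.table["end"] - grid.table["start"] != 350_000]
        assert len(tail) == 1 and tail["end"].iloc[0] == 1_000_000

    def test_snp_membership_spans_windows(self):
        """A SNP at 150,001 belongs to the windows starting at 0 and 100,000."""
        layout = GenomeLayout(lengths={"c": 1_000_000})
        variants = _variants({"c": [150_001]})
        grid = build_windows(layout, variants, min_snps=1)
        member = grid.table[(grid.table["hi"] - grid.table["lo"]) > 0]
        assert list(member["start"]) == [0, 100_000]

    def test_windows_below_min_snps_are_dropped(self):
        layout = GenomeLayout(lengths={"c": 1_000_000})
        variants = _variants({"c": [10_000, 20_000]})  # only 2 SNPs
        grid = build_windows(layout, variants, min_snps=3)
        assert grid.n_windows == 0

    def test_short_sequence_yields_single_window(self):
        layout = GenomeLayout(lengths={"c": 80_000})
        variants = _variants({"c": [10_000, 20_000, 30_000]})
        grid = build_windows(layout, variants)
        assert grid.n_windows == 1
        assert (grid.table.loc[0, "start"], grid.table.loc[0, "end"]) == (0, 80_000)


class TestWindowSizeChoice:
    def test_stabilization_rule_arithmetic(self):
        """Counts [100, 40, 10, 5, 4, 4]: the 4 -> 4 step is the first drop
        below 5%, so 250 kb is chosen."""
        sizes = [50_000, 100_000, 150_000, 200_000, 250_000, 300_000]
        chosen, ok = stabilization_choice(sizes, [100, 40, 10, 5, 4, 4])
        assert chosen == 250_000 and ok

    def test_never_stabilizing_counts_return_largest_with_warning(self):
        sizes = [50_000, 100_000, 150_000]
        chosen, ok = stabilization_choice(sizes, [80, 40, 20])
        assert chosen == 150_000 and not ok

    def test_uniform_20kb_density_stabilizes_near_350kb(self):
        """Random uniform SNP placement at ~20-kb spacing: the sparse-window
        count stabilizes in the 250-400 kb range (the study picked 350 kb)."""
        scenario = SimScenario(
            sample_sizes={"A": 4, "B": 4}, drift_f={"A": 0.1, "B": 0.1},
            layout=GenomeLayout(
                lengths={f"c{i}": 40_000_000 for i in range(5)}
            ),
            snp_spacing=20_000, seed=2,
        )
        panel, _ = simulate_panel(scenario)
        chosen, table, ok = choose_window_size(panel)
        assert ok
        assert 250_000 <= chosen <= 400_000
        assert table["n_sparse_windows"].is_monotonic_decreasing


class TestScanContrast:
    def test_m2_is_mean_of_pairwise_window_means(self):
        """Three breeds: the M2 score is the plain average of the per-pair
        window means, recomputed here from scratch per pair."""
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 30), (30, 30)).astype(np.int8)
        panel = build_panel(
            dos, breeds=["A"] * 10 + ["B"] * 10 + ["C"] * 10,
            positions=[(j + 1) * 10_000 for j in range(30)],
            seq_lengths={"chr1": 400_000},
        )
        grid = build_windows(panel.layout, panel.variants)
        score = scan_contrast(panel, grid, ContrastSpec("M2", frozenset("A")))
        idx = panel.breed_indices()
        for w, row in score.iterrows():
            pair_means = []
            for other in ("B", "C"):
                fst = hudson_fst_panel(panel, idx["A"], idx[other])["fst"]
                vals = fst.iloc[row.lo:row.hi].dropna()
                if len(vals) >= 3:
                    pair_means.append(vals.mean())
            assert row.fst == pytest.approx(np.mean(pair_means))

    def test_fixed_difference_gives_m1_score_one(self):
        dos = np.vstack([np.full((5, 12), 2), np.zeros((10, 12))]).astype(np.int8)
        panel = build_panel(
            dos, breeds=["A"] * 5 + ["B"] * 5 + ["C"] * 5,
            positions=[(j + 1) * 10_000 for j in range(12)],
            seq_lengths={"chr1": 400_000},
        )
        grid = build_windows(panel.layout, panel.variants)
        score = scan_contrast(panel, grid, ContrastSpec("M1", frozenset("A")))
        assert np.allclose(score["fst"], 1.0)

    def test_m2_exceeds_m1_on_study_shaped_panel(self, paper_like_panel):
        """Breed-vs-pool (M1) dilutes the contrast relative to the mean of
        pairwise comparisons (M2), so genome-mean M2 > M1 for every breed."""
        panel, _ = paper_like_panel
        grid = build_windows(panel.layout, panel.variants)
        for breed in ["CD", "IW", "BF"]:
            m1 = scan_contrast(panel, grid, ContrastSpec("M1", frozenset({breed})))
            m2 = scan_contrast(panel, grid, ContrastSpec("M2", frozenset({breed})))
            assert np.nanmean(m2["fst"]) > np.nanmean(m1["fst"])

    def test_m1_genome_mean_matches_drift_expectation(self):
        """Equal-size Balding-Nichols panel, common drift F: the M1 mean is
        close to F(1 + 1/(N-1))/2 — the pooled reference sits near the
        ancestral frequency, so only the focal breed's drift contributes
        (verified against the latent-frequency oracle below)."""
        F, n_breeds = 0.1, 15
        scenario = SimScenario(
            sample_sizes={f"B{i}": 20 for i in range(n_breeds)},
            drift_f={f"B{i}": F for i in range(n_breeds)},
            layout=GenomeLayout(lengths={"c1": 100_000_000}),
            snp_spacing=10_000, seed=6,
        )
        panel, truth = simulate_panel(scenario)
        grid = build_windows(panel.layout, panel.variants)
        m1 = scan_contrast(panel, grid, ContrastSpec("M1", frozenset({"B0"})))
        got = float(np.nanmean(m1["fst"]))
        # latent oracle: Hudson ratio from the true breed frequencies
        q = truth.breed_freqs.to_numpy()
        q1 = q[:, 0]
        qp = q[:, 1:].mean(axis=1)
        oracle = np.mean(
            ((q1 - qp) ** 2 - 0 - 0) / (q1 * (1 - qp) + qp * (1 - q1))
        )
        assert got == pytest.approx(oracle, abs=0.02)
        assert got < F  # well below the naive F expectation

    def test_unknown_breed_raises(self, paper_like_panel):
        panel, _ = paper_like_panel
        grid = build_windows(panel.layout, panel.variants)
        with pytest.raises(ValueError, match="ghost"):
            scan_contrast(panel, grid, ContrastSpec("M1", frozenset({"ghost"})))


class TestTopK:
    def test_study_scale_counts(self):
        """7,000 retained windows: 14 at the 99.8th and 70 at the 99.0th
        percentile; 70 single markers of 139,922 at the 99.95th."""
        assert top_k_count(7_000, 99.8) == 14
        assert top_k_count(7_000, 99.0) == 70
        assert top_k_count(139_922, 99.95) == 70

    def test_percentile_100_calls_nothing(self):
        assert top_k_count(7_000, 100.0) == 0


class TestRegionCalling:
    def _scores(self, rows):
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "fst"]
        )
        df.insert(0, "contrast", "M1:X")
        df["lo"] = 0
        df["hi"] = 3
        df["n_snps"] = 3
        df["n_valid"] = 3
        return df

    def test_expand_and_merge_interval_arithmetic(self):
        """Adjacent top windows at 1.0-1.35 Mb and 1.3-1.65 Mb expanded by
        200 kb merge into the single region 0.8-1.85 Mb."""
        layout = GenomeLayout(lengths={"c": 5_000_000})
        rows = [("c", 1_000_000, 1_350_000, 0.9), ("c", 1_300_000, 1_650_000, 0.8)]
        rows += [("c", s, s + 350_000, 0.01) for s in range(0, 900_000, 100_000)]
        regions = call_outlier_regions(self._scores(rows), 90.0, layout)
        top = [r for r in regions if r.start > 500_000]
        assert len(top) == 1
        bed = regions_to_bed(top)
        assert (bed.loc[0, "start"], bed.loc[0, "end"]) == (800_000, 1_850_000)

    def test_expansion_clamped_to_sequence(self):
        layout = GenomeLayout(lengths={"c": 1_000_000})
        rows = [("c", 0, 350_000, 0.9)]
        regions = call_outlier_regions(self._scores(rows), 50.0, layout)
        assert regions[0].start == 1
        assert regions[0].end == 550_000

    def test_all_equal_scores_tie_break_in_genomic_order(self):
        layout = GenomeLayout(lengths={"c": 5_000_000})
        rows = [("c", s, s + 350_000, 0.5) for s in range(0, 1_000_000, 100_000)]
        regions = call_outlier_regions(self._scores(rows), 99.0, layout)
        # k = ceil(10 * 0.01) = 1, first window in genomic order wins
        assert len(regions) == 1 and regions[0].start == 1

    def test_percentile_100_returns_empty(self):
        layout = GenomeLayout(lengths={"c": 5_000_000})
        rows = [("c", 0, 350_000, 0.5)]
        assert call_outlier_regions(self._scores(rows), 100.0, layout) == []

    def test_merge_conserves_covered_bases_against_base_set_oracle(self):
        """Merged regions cover exactly the union of member base sets."""
        layout = GenomeLayout(lengths={"c": 10_000})
        rng = np.random.default_rng(1)
        regions = []
        for _ in range(25):
            a = int(rng.integers(1, 9_000))
            b = min(10_000, a + int(rng.integers(1, 800)))
            regions.append(RegionCall("c", a, b, {"x"}, {"M1"}, 99.0))
        merged = merge_regions(regions, layout)
        oracle = set()
        for r in regions:
            oracle |= set(range(r.start, r.end + 1))
        got = set()
        for r in merged:
            span = set(range(r.start, r.end + 1))
            assert not (got & span), "merged regions must be disjoint"
            got |= span
        # abutting-interval merging may bridge a 0-length gap but never adds
        # or removes covered bases
        assert got == oracle

    def test_overlap_identical_lists_is_idempotent(self):
        layout = GenomeLayout(lengths={"c": 5_000_000})
        m1 = [RegionCall("c", 100, 500, {"a"}, {"M1"}, 99.8)]
        m2 = [RegionCall("c", 100, 500, {"a"}, {"M2"}, 99.8)]
        overlap, union = overlap_method_regions(m1, m2, layout)
        assert len(union) == 1 and len(overlap) == 1
        assert union[0].start == 100 and union[0].end == 500

    def test_overlap_disjoint_lists_is_empty(self):
        layout = GenomeLayout(lengths={"c": 5_000_000})
        m1 = [RegionCall("c", 100, 500, {"a"}, {"M1"}, 99.8)]
        m2 = [RegionCall("c", 2_000, 2_500, {"a"}, {"M2"}, 99.8)]
        overlap, union = overlap_method_regions(m1, m2, layout)
        assert overlap == [] and len(union) == 2

    def test_partially_overlapping_methods_union_flagged_both(self):
        layout = GenomeLayout(lengths={"c": 5_000_000})
        m1 = [RegionCall("c", 1, 500_000, {"a"}, {"M1"}, 99.8)]
        m2 = [RegionCall("c", 400_000, 900_000, {"a"}, {"M2"}, 99.8)]
        overlap, union = overlap_method_regions(m1, m2, layout)
        assert len(union) == 1
        assert union[0].start == 1 and union[0].end == 900_000
        assert union[0].methods == {"M1", "M2"}
        assert overlap == union


class TestSingleMarkers:
    def test_top_k_and_ordering(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(2_000)],
                "chrom": "c",
                "pos": np.arange(2_000) * 1_000 + 1,
                "fst": rng.uniform(0, 0.5, 2_000),
            }
        )
        out = single_marker_outliers(df, percentile=99.95)
        assert len(out) == 1  # ceil(2000 * 0.0005)
        assert out["fst"].iloc[0] == df["fst"].max()

    def test_ties_resolved_in_genomic_order(self):
        df = pd.DataFrame(
            {"id": list("abcd"), "chrom": "c", "pos": [1, 2, 3, 4],
             "fst": [0.5, 0.5, 0.5, 0.5]}
        )
        out = single_marker_outliers(df, percentile=50.0)
        assert list(out["id"]) == ["a", "b"]

    def test_single_extreme_snp_selected(self):
        df = pd.DataFrame(
            {"id": ["a", "b", "c"], "chrom": "c", "pos": [1, 2, 3],
             "fst": [0.0, 1.0, 0.0]}
        )
        out = single_marker_outliers(df, percentile=99.0)
        assert list(out["id"]) == ["b"]

    def test_nan_values_excluded_from_ranking(self):
        df = pd.DataFrame(
            {"id": ["a", "b"], "chrom": "c", "pos": [1, 2],
             "fst": [np.nan, 0.2]}
        )
        out = single_marker_outliers(df, percentile=50.0)
        assert list(out["id"]) == ["b"]


def test_planted_sweeps_recovered_by_both_methods():
    """Headline recovery property: 15 breeds (n = 20, background F = 0.1),
    five 350-kb sweeps planted in five breeds at focal frequency 0.98 with the
    other breeds intermediate — at least 4 of 5 sweeps are called at the
    99.8th percentile by M1 and by M2, and survive in their overlap."""
    n_breeds = 15
    names = [f"B{i}" for i in range(n_breeds)]
    layout = GenomeLayout(lengths={f"c{i}": 50_000_000 for i in range(20)})
    sweeps = [
        PlantedSweep(f"c{2 * k}", 10_000_001, 10_350_000, names[k], 0.98)
        for k in range(5)
    ]
    scenario = SimScenario(
        sample_sizes={b: 20 for b in names},
        drift_f={b: 0.1 for b in names},
        layout=layout, snp_spacing=20_000, sweeps=sweeps, seed=13,
    )
    panel, truth = simulate_panel(scenario)
    grid = build_windows(panel.layout, panel.variants)

    def hits(regions, sweep):
        return any(
            r.chrom == sweep.chrom
            and r.start <= sweep.end and r.end >= sweep.start
            for r in regions
        )

    n_m1 = n_m2 = n_both = 0
    for sweep in truth.sweeps:
        focal = frozenset({sweep.focal_breed})
        m1 = call_outlier_regions(
            scan_contrast(panel, grid, ContrastSpec("M1", focal)),
            99.8, panel.layout,
        )
        m2 = call_outlier_regions(
            scan_contrast(panel, grid, ContrastSpec("M2", focal)),
            99.8, panel.layout,
        )
        overlap, _ = overlap_method_regions(m1, m2, panel.layout)
        n_m1 += hits(m1, sweep)
        n_m2 += hits(m2, sweep)
        n_both += hits(overlap, sweep)
    assert n_m1 >= 4 and n_m2 >= 4 and n_both >= 4


def test_group_contrast_pools_focal_against_reference(paper_like_panel):
    panel, _ = paper_like_panel
    grid = build_windows(panel.layout, panel.variants)
    spec = ContrastSpec(
        "group", frozenset({"IW", "GW"}), name="group:albino"
    )
    score = scan_contrast(panel, grid, spec)
    assert score["contrast"].iloc[0] == "group:albino"
    assert np.nanmean(score["fst"]) > 0
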