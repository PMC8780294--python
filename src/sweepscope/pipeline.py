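"""End-to-end orchestration: QC -> diversity -> structure -> LD/Ne -> PCA scan
-> window scans -> region calls -> annotation -> optional ORA.

Everything is driven by a :class:`RunConfig` whose defaults are the scan's
canonical settings (call-rate 0.90, 350-kb/100-kb windows, >= 3 SNPs per
window, 99.8/99.0 window percentiles, 99.95 single-marker percentile, 200-kb
expansion).  A single seed governs every stochastic stage; per-stage seeds are
derived by stable hashing of the stage name so that disabling one stage never
perturbs another.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import ld_ne as ld_mod
from .genotype_io import GenotypePanel, GroupSpec, load_panel, qc_filter_samples
from .pca_outlier import bonferroni_outliers, fit_pca_zscores, mahalanobis_pvalues
from .popgen_stats import breed_summaries, fst_matrix, hudson_fst_panel
from .population_structure import mds_embed, nj_tree
from .sweep_scan import (
    ContrastSpec,
    build_windows,
    call_outlier_regions,
    merge_regions,
    overlap_method_regions,
    regions_to_bed,
    regions_to_frame,
    scan_contrast,
    single_marker_outliers,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed"]


class PipelineError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genotype_path: str = ""
    breed_map_path: str = ""
    layout_path: str = ""
    out_dir: str = "sweepscope_out"
    min_call_rate: float = 0.90
    window: int = 350_000
    step: int = 100_000
    min_snps: int = 3
    percentiles: tuple[float, float] = (99.8, 99.0)
    single_marker_percentile: float = 99.95
    expand_bp: int = 200_000
    pca_k: int = 10
    n_boot: int = 200
    seed: int = 0
    groups: list[dict] = field(default_factory=list)
    gff_path: str = ""
    gmt_path: str = ""
    run_ld: bool = True
    run_ora: bool = False
    run_plots: bool = False
    ld_max_dist: int = 300_000
    ld_bin_width: int = 50_000

    def group_specs(self) -> list[GroupSpec]:
        out = []
        for g in self.groups:
            ref = g.get("reference")
            out.append(
                GroupSpec(
                    name=g["name"],
                    focal=frozenset(g["focal"]),
                    reference=frozenset(ref) if ref else None,
                )
            )
        return out

    def config_hash(self) -> str:
        """Fingerprint of the analysis settings (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Stage-specific seed derived by stable hashing; always < 2**31."""
    return (seed ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][path.name] = int(len(df))


def run_pipeline(
    config: RunConfig, panel: GenotypePanel | None = None
) -> dict:
    """Run the full analysis; returns (and writes) the run manifest.

    ``panel`` may be passed directly (e.g. a simulated one); otherwise it is
    loaded from the configured paths.  Any stage failure raises
    :class:`PipelineError` naming the stage, after flagging the manifest
    incomplete on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {},
        "counts": {},
        "complete": False,
    }
    stage = "load"
    try:
        if panel is None:
            panel = load_panel(
                config.genotype_path, config.breed_map_path, config.layout_path
            )
        manifest["counts"]["samples_in"] = panel.n_samples
        manifest["counts"]["snps"] = panel.n_variants

        stage = "qc"
        panel, removed = qc_filter_samples(panel, config.min_call_rate)
        _write(removed, out / "qc_removed_samples.tsv", manifest)
        manifest["counts"]["samples_retained"] = panel.n_samples

        stage = "summaries"
        _write(breed_summaries(panel), out / "breed_summaries.tsv", manifest)

        stage = "fst_matrix"
        mat, store = fst_matrix(panel)
        mat.to_csv(out / "fst_matrix.tsv", sep="\t")
        manifest["outputs"]["fst_matrix.tsv"] = len(mat)

        stage = "nj_tree"
        tree = nj_tree(
            mat, store, n_boot=config.n_boot,
            seed=stage_seed(config.seed, "nj_tree"),
        )
        (out / "breeds.nwk").write_text(tree.newick() + "\n")
        manifest["outputs"]["breeds.nwk"] = 1

        stage = "mds"
        emb = mds_embed(panel, d=3)
        emb.coords.to_csv(out / "mds.tsv", sep="\t")
        manifest["outputs"]["mds.tsv"] = len(emb.coords)

        if config.run_ld:
            stage = "ld_ne"
            ne_rows = []
            for breed, rows in panel.breed_indices().items():
                bins = ld_mod.ld_decay(
                    panel, breed, config.ld_max_dist, config.ld_bin_width
                )
                bins.insert(0, "breed", breed)
                ne = ld_mod.ne_from_ld(bins, n_samples=len(rows))
                ne.insert(0, "breed", breed)
                ne_rows.append((bins, ne))
            _write(
                pd.concat([b for b, _ in ne_rows], ignore_index=True),
                out / "ld_decay.tsv", manifest,
            )
            _write(
                pd.concat([n for _, n in ne_rows], ignore_index=True),
                out / "ne_estimates.tsv", manifest,
            )

        stage = "pca_scan"
        model = mahalanobis_pvalues(fit_pca_zscores(panel, config.pca_k))
        outliers = bonferroni_outliers(model, alpha=0.1)
        _write(outliers, out / "pca_outliers.tsv", manifest)
        manifest["counts"]["pca_gif"] = round(float(model.gif), 4)

        stage = "windows"
        grid = build_windows(
            panel.layout, panel.variants, config.window, config.step,
            config.min_snps,
        )
        manifest["counts"]["windows_retained"] = grid.n_windows

        stage = "window_scans"
        breeds = panel.breeds
        scans: dict[str, pd.DataFrame] = {}
        for b in breeds:
            for kind in ("M1", "M2"):
                c = ContrastSpec(kind=kind, focal=frozenset({b}))
                scans[c.name] = scan_contrast(panel, grid, c, config.min_snps)
        for gs in config.group_specs():
            gs.validate_against(breeds)
            c = ContrastSpec(
                kind="group", focal=gs.focal, reference=gs.reference,
                name=f"group:{gs.name}",
            )
            scans[c.name] = scan_contrast(panel, grid, c, config.min_snps)
        all_scores = pd.concat(scans.values(), ignore_index=True)
        _write(
            all_scores.drop(columns=["lo", "hi"]),
            out / "window_scores.tsv", manifest,
        )

        stage = "region_calls"
        all_region_frames = []
        per_breed_overlap_counts = {}
        for pct in config.percentiles:
            union_all: list = []
            for b in breeds:
                m1 = call_outlier_regions(
                    scans[f"M1:{b}"], pct, panel.layout, config.expand_bp
                )
                m2 = call_outlier_regions(
                    scans[f"M2:{b}"], pct, panel.layout, config.expand_bp
                )
                ov, un = overlap_method_regions(m1, m2, panel.layout)
                union_all.extend(un)
                if pct == config.percentiles[0]:
                    per_breed_overlap_counts[b] = len(ov)
            merged = merge_regions(union_all, panel.layout)
            frame = regions_to_frame(merged)
            frame["percentile"] = pct
            all_region_frames.append(frame)
            manifest["counts"][f"regions_p{pct}"] = len(merged)
            regions_to_bed(merged).to_csv(
                out / f"regions_p{pct}.bed", sep="\t", index=False, header=False
            )
            manifest["outputs"][f"regions_p{pct}.bed"] = len(merged)
            if pct == config.percentiles[0]:
                top_regions = merged
        for name, scan in scans.items():
            if not name.startswith("group:"):
                continue
            for pct in config.percentiles:
                regs = call_outlier_regions(
                    scan, pct, panel.layout, config.expand_bp
                )
                frame = regions_to_frame(regs)
                frame["percentile"] = pct
                all_region_frames.append(frame)
        _write(
            pd.concat(all_region_frames, ignore_index=True),
            out / "regions.tsv", manifest,
        )
        manifest["counts"]["m1_m2_overlap_regions_per_breed"] = (
            per_breed_overlap_counts
        )

        stage = "single_markers"
        idx = panel.breed_indices()
        marker_frames = []
        for b in breeds:
            rest = np.concatenate([idx[x] for x in breeds if x != b])
            tab = hudson_fst_panel(panel, idx[b], rest)
            tab["chrom"] = panel.variants["chrom"].to_numpy()
            tab["pos"] = panel.variants["pos"].to_numpy()
            top = single_marker_outliers(tab, config.single_marker_percentile)
            top.insert(0, "breed", b)
            marker_frames.append(top)
        _write(
            pd.concat(marker_frames, ignore_index=True),
            out / "single_marker_outliers.tsv", manifest,
        )

        if config.gff_path:
            stage = "annotate"
            genes = annotate_mod.read_gff_genes(config.gff_path)
            hits = annotate_mod.intersect_genes(top_regions, genes)
            _write(hits, out / "region_genes.tsv", manifest)
            if config.run_ora and config.gmt_path:
                stage = "ora"
                library = annotate_mod.read_gmt(config.gmt_path)
                background = {g.symbol for g in genes}
                input_genes = set(hits["gene"]) & background
                gene_regions: dict[str, set] = {}
                for row in hits.itertuples(index=False):
                    gene_regions.setdefault(row.gene, set()).add(
                        (row.region_chrom, row.region_start, row.region_end)
                    )
                if input_genes:
                    filtered, full = annotate_mod.ora_fisher(
                        input_genes, background, library, gene_regions
                    )
                    _write(filtered, out / "ora_enriched.tsv", manifest)
                    _write(full, out / "ora_full.tsv", manifest)

        if config.run_plots:
            stage = "plots"
            from . import plots

            plots.manhattan_windows(
                all_scores[all_scores["contrast"].str.startswith("M1:")],
                panel.layout, out / "manhattan_m1.png",
            )
            manifest["outputs"]["manhattan_m1.png"] = 1

        manifest["complete"] = True
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc
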