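"""Multi-breed genotype simulator under the Balding-Nichols model.

Breed allele frequencies drift from a shared ancestral frequency p via
``q_b ~ Beta(p(1-F_b)/F_b, (1-p)(1-F_b)/F_b)``, so that ``E[q_b] = p`` and
``Var(q_b) = F_b * p(1-p)`` — the drift parameter F_b is, by construction, the
breed's expected differentiation from the ancestral pool, the quantity the
Hudson F_ST scan estimates.  Within a breed, genotypes are Binomial(2, q_b)
draws, optionally with inbreeding f_b: with probability f_b an individual's two
alleles are identical by descent (dosage 0 or 2), giving the classic
heterozygote deficit E[Ho] = (1 - f_b) * 2 q (1 - q).

Two kinds of features can be planted for parameter-recovery tests:

* **sweeps** — contiguous blocks where the focal breed's frequency is forced to
  a near-fixed target (ancestral frequency inside the block is pinned at 0.5 so
  the other breeds stay intermediate), emulating the window-level F_ST excess
  left by recent directional selection;
* **balanced loci** — blocks where a stated fraction of a breed's individuals
  is forced heterozygous, emulating loci maintained heterozygous (the English
  spotting KIT genotype En/en of spotted rabbit breeds being the motivating
  case).

Linkage disequilibrium is absent by default (SNPs independent); an optional
block-copy mode creates local LD solely to exercise the LD/Ne machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenomeLayout, GenotypePanel

__all__ = [
    "PlantedSweep",
    "BalancedLocus",
    "SimScenario",
    "SimTruth",
    "simulate_panel",
    "make_paper_like_scenario",
]


@dataclass(frozen=True)
class PlantedSweep:
    """A planted selection signature: focal breed driven to ``target_freq``."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    focal_breed: str
    target_freq: float = 0.98

    def __post_init__(self):
        if not 0 < self.target_freq < 1:
            raise ValueError("sweep target frequency must lie in (0, 1)")


@dataclass(frozen=True)
class BalancedLocus:
    """A planted balanced block: ``het_fraction`` of the breed forced heterozygous."""

    chrom: str
    start: int
    end: int
    breed: str
    het_fraction: float = 0.6


@dataclass
class SimScenario:
    """Everything needed to simulate one multi-breed panel, deterministically.

    ``sample_sizes`` maps breed -> n individuals; ``drift_f`` maps breed -> the
    Balding-Nichols F; ``inbreeding_f`` maps breed -> excess-homozygosity f
    (breeds absent from the dict get 0).  Ancestral frequencies are uniform on
    ``ancestral_range``.  SNPs are placed at jittered ~``snp_spacing`` bp
    intervals on every layout sequence.
    """

    sample_sizes: dict[str, int]
    drift_f: dict[str, float]
    layout: GenomeLayout
    inbreeding_f: dict[str, float] = field(default_factory=dict)
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    snp_spacing: int = 20_000
    missing_rate: float = 0.0
    sweeps: list[PlantedSweep] = field(default_factory=list)
    balanced_loci: list[BalancedLocus] = field(default_factory=list)
    ld_block_size: int = 0  # >0 switches on block-copy LD
    ld_block_rho: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for b, n in self.sample_sizes.items():
            if n < 2:
                raise ValueError(f"breed {b!r}: sample size must be >= 2")
        for b, f in self.drift_f.items():
            if not 0 <= f < 1:
                raise ValueError(f"breed {b!r}: drift F must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for feat in list(self.sweeps) + list(self.balanced_loci):
            if feat.chrom not in self.layout:
                raise ValueError(f"planted feature on unknown sequence {feat.chrom!r}")
            if not 1 <= feat.start <= feat.end <= self.layout.lengths[feat.chrom]:
                raise ValueError(
                    f"planted interval {feat.chrom}:{feat.start}-{feat.end} "
                    "outside layout"
                )

    @property
    def breeds(self) -> list[str]:
        return list(self.sample_sizes)


@dataclass
class SimTruth:
    """Ledger of what was planted, for parameter-recovery tests."""

    sweeps: list[PlantedSweep]
    balanced_loci: list[BalancedLocus]
    drift_f: dict[str, float]
    inbreeding_f: dict[str, float]
    breed_freqs: pd.DataFrame  # latent q_b per SNP per breed (breeds as columns)

    def to_tsv(self, path) -> None:
        rows = []
        for s in self.sweeps:
            rows.append(("sweep", s.chrom, s.start, s.end, s.focal_breed, s.target_freq))
        for b in self.balanced_loci:
            rows.append(("balanced", b.chrom, b.start, b.end, b.breed, b.het_fraction))
        pd.DataFrame(
            rows, columns=["kind", "chrom", "start", "end", "breed", "value"]
        ).to_csv(path, sep="\t", index=False)


def _place_snps(scenario: SimScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform-random SNP placement (Poisson-like gaps) at the target density.

    length/spacing SNPs per sequence, positions drawn uniformly and sorted —
    array SNPs are irregularly spaced, which is what makes sparse-window
    counting (window-size selection) non-trivial.
    """
    rows = []
    spacing = scenario.snp_spacing
    for name, length in scenario.layout.lengths.items():
        n_snp = max(int(length // spacing), 0)
        if n_snp == 0:
            continue
        pos = np.sort(rng.integers(1, length + 1, size=n_snp))
        for k, p in enumerate(pos):
            rows.append((f"{name}_{k}_{p}", name, int(p)))
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    df["a1"] = "A"
    df["a2"] = "G"
    return df


def simulate_panel(scenario: SimScenario) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a panel under the scenario; bit-identical for a given seed."""
    rng = np.random.default_rng(scenario.seed)
    variants = _place_snps(scenario, rng)
    m = len(variants)
    if m == 0:
        raise ValueError("layout/spacing combination yields zero SNPs")

    lo, hi = scenario.ancestral_range
    p_anc = rng.uniform(lo, hi, size=m)

    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()

    sweep_masks: list[tuple[PlantedSweep, np.ndarray]] = []
    for s in scenario.sweeps:
        mask = (chrom == s.chrom) & (pos >= s.start) & (pos <= s.end)
        sweep_masks.append((s, mask))
        p_anc[mask] = 0.5  # non-focal breeds stay intermediate in the block
    for bl in scenario.balanced_loci:
        # balanced polymorphisms live at intermediate background frequency:
        # the locus must differ from its neighbours by genotype composition
        # (excess heterozygotes), not by allele frequency
        mask = (chrom == bl.chrom) & (pos >= bl.start) & (pos <= bl.end)
        p_anc[mask] = 0.5

    breeds = scenario.breeds
    q = np.empty((len(breeds), m))
    for bi, b in enumerate(breeds):
        f = scenario.drift_f.get(b, 0.0)
        if f == 0.0:
            q[bi] = p_anc
        else:
            a = p_anc * (1 - f) / f
            c = (1 - p_anc) * (1 - f) / f
            q[bi] = rng.beta(a, c)
    for s, mask in sweep_masks:
        q[breeds.index(s.focal_breed), mask] = s.target_freq

    samples: list[str] = []
    breed_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for bi, b in enumerate(breeds):
        n = scenario.sample_sizes[b]
        ids = [f"{b}_{i:03d}" for i in range(n)]
        samples.extend(ids)
        for s in ids:
            breed_of[s] = b
        qb = q[bi]
        f_ib = scenario.inbreeding_f.get(b, 0.0)
        geno = rng.binomial(2, qb[None, :], size=(n, m)).astype(np.int8)
        if f_ib > 0:
            ibd = rng.random((n, m)) < f_ib
            hom = (rng.random((n, m)) < qb[None, :]).astype(np.int8) * 2
            geno = np.where(ibd, hom, geno)
        blocks.append(geno)
    dosages = np.vstack(blocks)

    if scenario.ld_block_size > 0:
        _apply_block_ld(dosages, chrom, pos, scenario, rng)

    for bl in scenario.balanced_loci:
        mask = (chrom == bl.chrom) & (pos >= bl.start) & (pos <= bl.end)
        rows = [i for i, s in enumerate(samples) if breed_of[s] == bl.breed]
        if not rows or not mask.any():
            continue
        sub = dosages[np.ix_(rows, np.where(mask)[0])]
        het = rng.random(sub.shape) < bl.het_fraction
        hom = (rng.random(sub.shape) < 0.5).astype(np.int8) * 2
        dosages[np.ix_(rows, np.where(mask)[0])] = np.where(het, 1, hom)

    if scenario.missing_rate > 0:
        miss = rng.random(dosages.shape) < scenario.missing_rate
        dosages[miss] = MISSING

    panel = GenotypePanel(
        dosages=dosages,
        samples=samples,
        variants=variants,
        breed_of=breed_of,
        layout=scenario.layout,
    )
    truth = SimTruth(
        sweeps=list(scenario.sweeps),
        balanced_loci=list(scenario.balanced_loci),
        drift_f=dict(scenario.drift_f),
        inbreeding_f=dict(scenario.inbreeding_f),
        breed_freqs=pd.DataFrame(q.T, columns=breeds),
    )
    return panel, truth


def _apply_block_ld(
    dosages: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> None:
    """Copy-with-noise within blocks: each SNP in a block replicates the block's
    first SNP with probability ``ld_block_rho`` per individual, creating local
    r² without touching between-block independence."""
    size = scenario.ld_block_size
    for name in np.unique(chrom):
        idx = np.where(chrom == name)[0]
        block_id = pos[idx] // size
        for b in np.unique(block_id):
            members = idx[block_id == b]
            if len(members) < 2:
                continue
            anchor = dosages[:, members[0]]
            for j in members[1:]:
                copy = rng.random(anchor.shape[0]) < scenario.ld_block_rho
                dosages[copy, j] = anchor[copy]


# ---------------------------------------------------------------------------
# study-shaped scenario factory

# Breed acronyms and sample sizes of the 15-breed rabbit panel the package
# emulates (three commercial meat lines + twelve fancy breeds, 660 animals).
PAPER_BREEDS: dict[str, int] = {
    "ISI": 20, "ISP": 93, "IW": 256, "BH": 24, "BF": 6,
    "CdA": 19, "CG": 79, "CD": 20, "DL": 20, "ER": 20,
    "GG": 27, "GW": 20, "RE": 19, "RH": 28, "TH": 9,
}

# Drift F per breed, graded 0.08-0.25 so single-breed mean F_ST spans roughly
# 0.09-0.23 across breeds (least drifted: the large commercial white line;
# most drifted: the rare fancy breeds).
PAPER_DRIFT_F: dict[str, float] = {
    "IW": 0.08, "ISP": 0.10, "CG": 0.11, "GG": 0.11, "CD": 0.12,
    "DL": 0.12, "GW": 0.12, "RE": 0.12, "ISI": 0.12, "RH": 0.15,
    "BH": 0.18, "CdA": 0.19, "TH": 0.18, "ER": 0.22, "BF": 0.25,
}

# Positive within-breed inbreeding for the four breeds with printed
# heterozygote deficits (Coloured Dwarf, Dwarf Lop, Ermine, Rex).
PAPER_INBREEDING_F: dict[str, float] = {"CD": 0.17, "DL": 0.12, "ER": 0.09, "RE": 0.08}

# 21 autosome lengths (bp) approximating the rabbit assembly's relative sizes
# (total ~2.66 Gb), plus two unplaced scaffolds.
_BASE_CHROM_LENGTHS = [
    194, 174, 156, 91, 38, 27, 173, 111, 116, 48,
    88, 156, 144, 164, 110, 85, 85, 70, 57, 33, 16,
]  # Mb


def make_paper_like_scenario(
    scale: float = 0.02,
    seed: int = 0,
    n_sweeps: int = 5,
    with_balanced_locus: bool = True,
    missing_rate: float = 0.01,
) -> SimScenario:
    """A scenario shaped like the 15-breed rabbit study, genome scaled by ``scale``.

    At ``scale=1`` the layout totals ~2.7 Gb with ~20-kb SNP spacing (~130 k
    SNPs); tests use small scales.  Plants ``n_sweeps`` 350-kb sweeps in
    distinct breeds on distinct chromosomes and (optionally) one KIT-like
    balanced locus in the RH breed at heterozygote fraction 0.6.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    lengths: dict[str, int] = {}
    flags: dict[str, bool] = {}
    for i, mb in enumerate(_BASE_CHROM_LENGTHS, 1):
        L = int(mb * 1_000_000 * scale)
        if L >= 700_000:  # keep sequences that can host at least one window
            lengths[f"OCU{i}"] = L
            flags[f"OCU{i}"] = True
    if not any(flags.values()):
        raise ValueError(
            "scale too small: no assembled chromosome can host a 350-kb window"
        )
    for name, mb in (("Un0267", 3.0), ("Un0030", 2.1)):
        L = int(mb * 1_000_000 * max(scale, 0.35))
        lengths[name] = L
        flags[name] = False
    layout = GenomeLayout(lengths=lengths, is_chromosome=flags)

    spacing = 20_000
    min_len = min(lengths.values())
    if min_len // spacing < 3:
        raise ValueError("scale too small: fewer than 3 SNPs per window possible")

    rng = np.random.default_rng(seed)
    sweep_breeds = ["CD", "BH", "RE", "GW", "ISI", "ER", "TH", "CG"][: max(n_sweeps, 0)]
    chroms = [c for c in lengths if flags[c]]
    sweeps = []
    for k, b in enumerate(sweep_breeds):
        chromosome = chroms[k % len(chroms)]
        L = lengths[chromosome]
        width = 350_000
        start = int(rng.integers(1, max(L - width, 2)))
        sweeps.append(
            PlantedSweep(
                chrom=chromosome, start=start, end=min(start + width - 1, L),
                focal_breed=b, target_freq=0.98,
            )
        )
    balanced = []
    if with_balanced_locus:
        chromosome = chroms[-1]
        L = lengths[chromosome]
        start = max(1, L // 2)
        balanced.append(
            BalancedLocus(
                chrom=chromosome, start=start,
                end=min(start + 350_000 - 1, L), breed="RH", het_fraction=0.6,
            )
        )
    return SimScenario(
        sample_sizes=dict(PAPER_BREEDS),
        drift_f=dict(PAPER_DRIFT_F),
        inbreeding_f=dict(PAPER_INBREEDING_F),
        layout=layout,
        snp_spacing=spacing,
        missing_rate=missing_rate,
        sweeps=sweeps,
        balanced_loci=balanced,
        seed=seed,
    )
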