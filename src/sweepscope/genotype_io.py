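"""Genotype panel containers and I/O.

A :class:`GenotypePanel` holds diploid biallelic SNP genotypes for a set of
samples assigned to populations (breeds), as a samples x SNPs dosage matrix
counting copies of the A1/ALT allele (0, 1, 2, or :data:`MISSING`).  Panels can
be read from and written to PLINK 1 binary (BED/BIM/FAM, SNP-major) or plain
VCF, together with a two-column sample->breed map and a genome layout listing
sequence lengths.

All downstream statistics skip missing cells; no minor-allele-frequency filter
is applied anywhere by default.  Positions are stored 1-based as in BIM/VCF.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenomeLayout",
    "GenotypePanel",
    "GroupSpec",
    "PanelFormatError",
    "load_panel",
    "qc_filter_samples",
    "write_panel",
    "read_breed_map",
    "read_layout",
    "parse_group_spec",
]

#: Sentinel for a missing genotype in the dosage matrix (int8).
MISSING: int = -1


class PanelFormatError(ValueError):
    """A genotype, breed-map or layout file is malformed or inconsistent."""


@dataclass(frozen=True)
class GenomeLayout:
    """Sequence names, lengths (bp) and assembled-chromosome flags.

    ``lengths`` maps sequence name -> length; ``is_chromosome`` maps name ->
    True for assembled chromosomes, False for unplaced scaffolds.  Iteration
    order of ``lengths`` defines the canonical sequence order.
    """

    lengths: dict[str, int]
    is_chromosome: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.lengths) == 0:
            raise ValueError("layout must contain at least one sequence")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"sequence {name!r} has non-positive length {length}")
        if not self.is_chromosome:
            object.__setattr__(
                self, "is_chromosome", {n: True for n in self.lengths}
            )

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    def order_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.lengths)}

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


@dataclass
class GenotypePanel:
    """Samples x SNPs dosage panel with breed assignments and genome layout.

    Attributes
    ----------
    dosages : (n_samples, n_variants) int8 array
        Count of A1/ALT alleles per genotype; ``MISSING`` (-1) for no-calls.
    samples : list of sample ids, ordered as in the genotype file.
    variants : DataFrame with columns ``id, chrom, pos, a1, a2``,
        sorted by (layout sequence order, position); ``pos`` is 1-based.
    breed_of : sample id -> breed label (every sample has exactly one).
    layout : GenomeLayout covering every variant's sequence.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame
    breed_of: dict[str, str]
    layout: GenomeLayout

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError("dosage rows != number of samples")
        if m != len(self.variants):
            raise ValueError("dosage columns != number of variants")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or the missing sentinel")
        missing_breed = [s for s in self.samples if s not in self.breed_of]
        if missing_breed:
            raise PanelFormatError(
                f"samples without a breed label: {missing_breed[:5]}"
            )
        unknown_seq = set(self.variants["chrom"]) - set(self.layout.lengths)
        if unknown_seq:
            raise PanelFormatError(
                f"variants on sequences absent from layout: {sorted(unknown_seq)[:5]}"
            )
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be positive integers")
        order = self.layout.order_index()
        chrom_idx = self.variants["chrom"].map(order).to_numpy()
        pos = self.variants["pos"].to_numpy()
        key = np.lexsort((pos, chrom_idx))
        if not np.array_equal(key, np.arange(m)):
            # enforce canonical (sequence, position) order
            self.variants = self.variants.iloc[key].reset_index(drop=True)
            self.dosages = self.dosages[:, key]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def breeds(self) -> list[str]:
        """Breed labels in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.breed_of[s], None)
        return list(seen)

    def breed_indices(self) -> dict[str, np.ndarray]:
        """Map breed -> integer row indices of its samples."""
        idx: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            idx.setdefault(self.breed_of[s], []).append(i)
        return {b: np.asarray(v, dtype=np.intp) for b, v in idx.items()}

    def subset_samples(self, keep: list[str]) -> "GenotypePanel":
        keep_set = set(keep)
        rows = [i for i, s in enumerate(self.samples) if s in keep_set]
        return GenotypePanel(
            dosages=self.dosages[rows, :].copy(),
            samples=[self.samples[i] for i in rows],
            variants=self.variants.copy(),
            breed_of={s: self.breed_of[s] for s in (self.samples[i] for i in rows)},
            layout=self.layout,
        )

    def call_rates(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotypes."""
        return (self.dosages != MISSING).mean(axis=1)

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.samples == other.samples
            and self.breed_of == other.breed_of
            and np.array_equal(self.dosages, other.dosages)
            and list(self.variants["id"]) == list(other.variants["id"])
            and list(self.variants["chrom"]) == list(other.variants["chrom"])
            and list(self.variants["pos"]) == list(other.variants["pos"])
        )


@dataclass(frozen=True)
class GroupSpec:
    """A named group contrast: focal breed set vs reference breed set.

    ``reference`` of ``None`` means "all other breeds in the panel".
    """

    name: str
    focal: frozenset[str]
    reference: frozenset[str] | None = None

    def __post_init__(self):
        if not self.focal:
            raise ValueError(f"group {self.name!r}: empty focal set")
        if self.reference is not None:
            if not self.reference:
                raise ValueError(f"group {self.name!r}: empty reference set")
            if self.focal & self.reference:
                raise ValueError(
                    f"group {self.name!r}: focal and reference sets overlap"
                )

    def resolve_reference(self, breeds: list[str]) -> frozenset[str]:
        if self.reference is not None:
            return self.reference
        return frozenset(breeds) - self.focal

    def validate_against(self, breeds: list[str]) -> None:
        known = set(breeds)
        unknown = (self.focal | (self.reference or frozenset())) - known
        if unknown:
            raise PanelFormatError(
                f"group {self.name!r} names unknown breeds: {sorted(unknown)}"
            )


# ---------------------------------------------------------------------------
# metadata files

def read_breed_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column ``sample<TAB>breed`` map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected 'sample<TAB>breed', got {line!r}"
                )
            out[parts[0]] = parts[1]
    if not out:
        raise PanelFormatError(f"{path}: empty breed map")
    return out


def read_layout(path: str | os.PathLike) -> GenomeLayout:
    """Read a ``name<TAB>length[<TAB>{chrom|scaffold}]`` layout file."""
    lengths: dict[str, int] = {}
    flags: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}"
                )
            name = parts[0]
            if name in lengths:
                raise PanelFormatError(f"{path}:{lineno}: duplicate sequence {name!r}")
            try:
                lengths[name] = int(parts[1])
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}:{lineno}: bad length {parts[1]!r}"
                ) from exc
            kind = parts[2] if len(parts) > 2 else "chrom"
            flags[name] = kind != "scaffold"
    return GenomeLayout(lengths=lengths, is_chromosome=flags)


def write_layout(layout: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in layout.lengths.items():
            kind = "chrom" if layout.is_chromosome.get(name, True) else "scaffold"
            fh.write(f"{name}\t{length}\t{kind}\n")


def write_breed_map(breed_of: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, breed in breed_of.items():
            fh.write(f"{sample}\t{breed}\n")


def parse_group_spec(text: str) -> list[GroupSpec]:
    """Parse group contrasts, one per line: ``name: breedA+breedB vs rest``.

    The reference side is either ``rest`` (all other breeds) or an explicit
    ``+``-joined breed list.
    """
    groups: list[GroupSpec] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise PanelFormatError(f"group spec line {lineno}: missing ':'")
        name, _, rhs = line.partition(":")
        if " vs " not in rhs:
            raise PanelFormatError(f"group spec line {lineno}: missing 'vs'")
        lhs, _, ref = rhs.partition(" vs ")
        focal = frozenset(b.strip() for b in lhs.strip().split("+") if b.strip())
        ref = ref.strip()
        reference = (
            None
            if ref == "rest"
            else frozenset(b.strip() for b in ref.split("+") if b.strip())
        )
        groups.append(GroupSpec(name=name.strip(), focal=focal, reference=reference))
    return groups


# ---------------------------------------------------------------------------
# PLINK 1 binary codec (SNP-major)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00=hom A1/A1, 01=missing, 10=het, 11=hom A2/A2.
# Dosage counts A1 alleles.
_CODE_TO_DOSE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def _read_plink(prefix: str) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    samples = list(fam["iid"])
    n, m = len(samples), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PanelFormatError(
                f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1 BED)"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise PanelFormatError(
            f"{prefix}.bed: expected {bytes_per_snp * m} data bytes, got {raw.size}"
        )
    raw = raw.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSE[codes[:, :n]].T.copy()  # samples x variants
    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    return dosages, samples, variants


def _write_plink(panel: GenotypePanel, prefix: str) -> None:
    n, m = panel.n_samples, panel.n_variants
    with open(prefix + ".fam", "w") as fh:
        for s in panel.samples:
            fh.write(f"{panel.breed_of[s]} {s} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for row in panel.variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    codes = np.empty((m, n), dtype=np.uint8)
    dos = panel.dosages.T  # variants x samples
    for dose, code in _DOSE_TO_CODE.items():
        codes[dos == dose] = code
    pad = (-n) % 4
    if pad:
        codes = np.hstack(
            [codes, np.ones((m, pad), dtype=np.uint8)]  # pad with missing (01)
        )
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF codec

def _read_vcf(path: str) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    doses = []
    for rec_index, rec in enumerate(vcf):
        alts = rec.ALT
        if len(alts) != 1:
            raise PanelFormatError(
                f"{path}: record {rec_index} ({rec.CHROM}:{rec.POS}) is not biallelic"
            )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        d = np.full(gt.shape, MISSING, dtype=np.int8)
        d[gt == 0] = 0
        d[gt == 1] = 1
        d[gt == 3] = 2
        doses.append(d)
        rows.append(
            (rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, alts[0], rec.REF)
        )
    if not rows:
        raise PanelFormatError(f"{path}: no variant records")
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "a1", "a2"])
    dosages = np.vstack(doses).T.copy()
    return dosages, samples, variants


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(panel: GenotypePanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscope\n")
        for name, length in panel.layout.lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        dos = panel.dosages
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            gts = "\t".join(_GT_STRING[int(d)] for d in dos[:, j])
            # a1 is the counted (ALT) allele, a2 the reference
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.a2}\t{row.a1}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# public API

def load_panel(
    genotype_path: str | os.PathLike,
    breed_map_path: str | os.PathLike,
    layout_path: str | os.PathLike,
) -> GenotypePanel:
    """Load a genotype panel from PLINK 1 binary or VCF plus metadata files.

    ``genotype_path`` is either a PLINK prefix (or any of its three member
    files) or a ``.vcf``/``.vcf.gz`` path.  Sample order follows the genotype
    file; variants are sorted by (layout sequence order, position).

    Raises
    ------
    PanelFormatError
        For malformed files, samples missing from the breed map, breed-map
        samples absent from the genotype file, or variants on sequences not in
        the layout.
    """
    genotype_path = str(genotype_path)
    if genotype_path.endswith((".vcf", ".vcf.gz")):
        dosages, samples, variants = _read_vcf(genotype_path)
    else:
        prefix = genotype_path
        for ext in (".bed", ".bim", ".fam"):
            if prefix.endswith(ext):
                prefix = prefix[: -len(ext)]
                break
        dosages, samples, variants = _read_plink(prefix)

    breed_map = read_breed_map(breed_map_path)
    layout = read_layout(layout_path)

    unknown = sorted(set(breed_map) - set(samples))
    if unknown:
        raise PanelFormatError(
            f"breed map lists samples absent from the genotype file: {unknown[:5]}"
        )
    unlabelled = [s for s in samples if s not in breed_map]
    if unlabelled:
        raise PanelFormatError(
            f"genotype samples missing from breed map: {unlabelled[:5]}"
        )
    return GenotypePanel(
        dosages=dosages,
        samples=samples,
        variants=variants,
        breed_of={s: breed_map[s] for s in samples},
        layout=layout,
    )


def qc_filter_samples(
    panel: GenotypePanel, min_call_rate: float = 0.90
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Retain samples whose call rate is strictly greater than ``min_call_rate``.

    Returns the filtered panel and a removal report (sample, breed, call_rate)
    for the samples dropped.  The variant set is unchanged.  A sample whose
    call rate equals the threshold exactly is removed ("higher than" is
    strict).
    """
    if not 0 <= min_call_rate <= 1:
        raise ValueError("min_call_rate must be in [0, 1]")
    rates = panel.call_rates()
    keep_mask = rates > min_call_rate
    if not keep_mask.any():
        raise ValueError(
            f"all {panel.n_samples} samples fall at or below call rate "
            f"{min_call_rate}"
        )
    removed = pd.DataFrame(
        {
            "sample": [s for s, k in zip(panel.samples, keep_mask) if not k],
            "breed": [
                panel.breed_of[s] for s, k in zip(panel.samples, keep_mask) if not k
            ],
            "call_rate": rates[~keep_mask],
        }
    )
    if keep_mask.all():
        return panel, removed
    kept = [s for s, k in zip(panel.samples, keep_mask) if k]
    return panel.subset_samples(kept), removed


def write_panel(
    panel: GenotypePanel,
    out_path: str | os.PathLike,
    format: str = "plink-binary",
    write_metadata: bool = True,
) -> None:
    """Write a panel as PLINK 1 binary or VCF, plus breed map and layout files.

    ``out_path`` is a PLINK prefix or a ``.vcf`` path.  When ``write_metadata``
    is set, ``<base>.breeds.tsv`` and ``<base>.layout.tsv`` are written next to
    the genotype file so that :func:`load_panel` can round-trip.
    """
    if panel.n_variants == 0:
        raise ValueError("refusing to write a panel with no variants")
    out_path = str(out_path)
    if format == "plink-binary":
        prefix = out_path
        _write_plink(panel, prefix)
        base = prefix
    elif format == "vcf":
        if not out_path.endswith(".vcf"):
            out_path += ".vcf"
        _write_vcf(panel, out_path)
        base = out_path[: -len(".vcf")]
    else:
        raise ValueError(f"unknown format {format!r} (use 'plink-binary' or 'vcf')")
    if write_metadata:
        write_breed_map(panel.breed_of, base + ".breeds.tsv")
        write_layout(panel.layout, base + ".layout.tsv")
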