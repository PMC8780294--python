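# Methods

`sweepscope` implements a breed-differentiation genome scan for SNP-array
panels: per-breed diversity, Hudson F_ST per SNP / per sliding window under
several contrast schemes, percentile-based region calling, a PCA–Mahalanobis
outlier scan, breed trees and MDS, LD decay with Sved-style Ne, and gene
annotation with Fisher's-exact over-representation.  Because suitable
multi-breed rabbit datasets are typically available only on request, the
package ships a Balding–Nichols simulator that reproduces the statistical
structure the scan assumes, so every stage is testable end to end.

## Hudson F_ST

For a biallelic SNP with allele frequencies p1, p2 estimated from n1, n2
called alleles,

    N = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    D = p1(1−p2) + p2(1−p1),   F_ST = N / D.

The estimator is insensitive to unequal sample sizes, which matters when
breeds of 6 and 256 animals are contrasted.  A value is undefined when D = 0
(monomorphic across both sides) or when either side has fewer than 4 called
alleles (the n−1 correction needs two genotypes); negative values are kept.

**Averaging.** Genome-wide, per-window and per-pair summaries are, by
default, unweighted means of per-SNP ratios ("average of ratios"), matching
the way SNP-array scans conventionally average F_ST across markers.  This
average is *not* an unbiased estimator of the island-model drift parameter:
under Balding–Nichols drift F = 0.2 (10 k SNPs, n = 100 per breed) the
mean-of-ratios gives ≈ 0.15 while the ratio-of-sums ("Bhatia") form, exposed
via `ratio_of_averages=True`, recovers 0.20 ± 0.02.  Parameter-recovery tests
therefore use the ratio-of-sums form; scan outputs keep the conventional
average.  Both forms are invariant to side swaps and allele-label flips.

## Contrast schemes

* **M1** — focal breed vs all remaining samples pooled.  Because the pooled
  reference sits near the ancestral frequency, the expected M1 value under
  equal-drift Balding–Nichols is ≈ F(1 + 1/(N−1))/2, i.e. roughly half the
  pairwise expectation — M1 measures the focal breed's own drift.
* **M2** — per window, the unweighted mean of the focal breed's N−1 pairwise
  window F_ST values.  Each pairwise window mean requires ≥ 3 defined per-SNP
  values; the M2 score averages the pairs that are defined and is undefined
  when none is.  Since each pairwise term carries both breeds' drift, M2
  genome means exceed M1 genome means — an ordering the test suite asserts
  for every breed.
* **group** — a pooled focal breed set vs a pooled reference set (or all
  remaining breeds), scored like M1.

## Window scan and region calling

Windows of width w = 350 kb slide with step s = 100 kb (w/s = 3.5, so each
SNP falls in 3–4 windows); windows with fewer than 3 SNPs are never scored.
The window-size selection procedure counts, for candidate sizes 50–500 kb
(step = size/3.5), the windows with < 3 SNPs and picks the smallest size
whose successor's count has dropped by < 5%.  At ~20-kb random uniform SNP
spacing this stabilizes at 350 kb, with ≈ 17.5 SNPs per window.

Percentile thresholds (99.8 strict, 99.0 suggestive for windows; 99.95 for
single markers) are implemented as a top-k rank rule,
k = ceil(W·(1 − pct/100)), ties broken by genomic order — this reproduces
exact per-contrast window counts (14 and 70 of 7,000) rather than an
interpolated quantile.  Called windows are expanded by 200 kb per side (a
hedge against assembly misplacement of small contigs), clamped to the
sequence, and merged treating abutting intervals as overlapping.  Method
overlap keeps union regions supported by at least one region from each of M1
and M2.  Coordinates are 0-based half-open internally, reported 1-based
inclusive (BED output is 0-based half-open).

A terminal partial window is generated when the last full window leaves
uncovered bases; with the ≥ 3 SNP rule it rarely survives.

## PCA–Mahalanobis outlier scan

Genotypes are standardized per SNP (impute missing by the mean, center by
2p̂, scale by sqrt(2p̂(1−p̂))); SNPs with MAF < 1/(2n) are excluded from the
scan only.  z_jk is the regression t-statistic of SNP j on the k-th of K
orthonormal principal-component score vectors (t-statistics make the z-score
covariance ≈ I under the null).  D_j² = (z_j − z̄)ᵀ Σ⁻¹ (z_j − z̄) with Σ the
sample covariance (a MAD-based robust option exists).  A genomic inflation
factor GIF = median(D²)/median(χ²_K) recalibrates the χ²_K tail before
p-values — without it the scan is anti-conservative under drift.  Outliers
satisfy p < α/L with α = 0.1.  A scree-elbow helper suggests K (largest k
whose eigenvalue drop exceeds 2% of the spectrum range, structural zero
eigenvalues of the centered decomposition excluded); the pipeline takes K
from configuration (default 10).

## Trees, MDS, LD and Ne

The breed tree is Saitou–Nei neighbour joining on the breed × breed mean
F_ST matrix (negative branch lengths clamped to zero with transfer to the
sibling edge).  Bootstrap support resamples SNP columns with replacement —
the distance is a per-SNP average, so the SNP is the natural resampling
unit — rebuilds the matrix from the per-pair per-SNP store and scores
bipartitions; 200 replicates by default in tests, 10,000 for full fidelity.

MDS is classical (Torgerson) scaling of the 1 − IBS distance over all
samples, IBS being the mean over co-called SNPs of (2 − |d_i − d_j|)/2;
exact on Euclidean inputs (asserted to 1e-9 on planar configurations).

LD r² is the squared sample correlation of dosage vectors over co-called
individuals (composite genotype r², no phasing), same-chromosome pairs only,
aggregated in 50-kb half-open distance bins up to 300 kb by default.  Ne per
bin inverts the Sved relationship E[r²] = 1/(α + 4Ne·c) + 1/n with
c = mean pair distance × 1e-8 Morgans (fixed 1 cM/Mb map), sample-size
adjustment r²_adj = r² − 1/n, t = 1/(2c) generations ago, and
Ne = (1/(4c))(1/r²_adj − α).  α defaults to 2.2 (mutation-corrected); α = 2
gives the textbook form.  Bins whose inversion yields Ne ≤ 0 are flagged
undefined.  The inversion is the exact inverse of the forward map (asserted
to 1e-9).

## Annotation and over-representation

Genes (type `gene`, protein-coding by default) are read from GFF3 and
assigned to regions by ≥ 1 bp overlap of 1-based inclusive intervals — no
promoter flank, since regions are already ±200-kb expanded.  Unplaced
scaffolds are treated exactly like chromosomes.  ORA uses the one-sided
Fisher's exact (hypergeometric upper tail) against a user-supplied GMT
library, Benjamini–Hochberg adjustment, and reports terms with ≥ 2 overlap
genes drawn from ≥ 2 distinct regions at adjusted p < 0.05 (the unfiltered
table is also returned).  The background defaults to all protein-coding
genes in the GFF.

## Synthetic panels

Per SNP, an ancestral frequency p ~ Uniform(0.05, 0.95); per breed b,
q_b ~ Beta(p(1−F_b)/F_b, (1−p)(1−F_b)/F_b), so E[q_b] = p and
Var(q_b) = F_b·p(1−p).  Genotypes are Binomial(2, q_b); with inbreeding f_b
an individual's two alleles are identical by descent with probability f_b
(E[Ho] = (1−f_b)·2q(1−q)).  SNP positions are uniform-random at the target
density (~20 kb), which is what makes sparse-window counting informative.
Missingness is i.i.d.  Everything is deterministic given the seed.

Planted features: **sweeps** pin the ancestral frequency at 0.5 inside the
block and force the focal breed to the target frequency (0.98) — frequency
overrides, not trajectory simulations; sufficient to create the window-level
excess the scan detects.  **Balanced loci** force a stated fraction of a
breed's individuals heterozygous, with the block's ancestral frequency also
pinned at 0.5: a balanced polymorphism differs from its neighbours in
genotype composition, not allele frequency, which is exactly why the F_ST
scan should not (and does not) call it — the negative-control property the
suite asserts over 20 replicates.

`make_paper_like_scenario` builds a 15-breed panel (sample sizes 20, 93,
256, 24, 6, 19, 79, 20, 20, 20, 27, 20, 19, 28, 9; total 660) with drift
graded F_b = 0.08–0.25 (the large commercial white line least drifted, the
rare fancy breeds most), inbreeding f_b ∈ {0.17, 0.12, 0.09, 0.08} for the
four breeds with heterozygote deficits, a 21-autosome layout (~2.14 Gb of
assembled chromosomes at scale 1, scaled down for tests) plus two token
unplaced scaffolds, five planted sweeps and one KIT-like balanced locus.
Under this model the emulated M1 genome means span ≈ 0.04–0.12: the
single-breed-vs-pool contrast measures roughly half the focal drift (see
above), so the absolute level sits below real-data tables while the breed
*ordering* is preserved.  LD is absent by default (independent SNPs); an
optional block-copy mode creates local LD solely to exercise the LD/Ne code.

What passing tests do **not** show about real data: the simulator has no
linkage structure (beyond the optional toy mode), no ascertainment bias in
the SNP frequency spectrum, no relatedness within breeds, and token rather
than realistic unplaced-scaffold content; absolute diversity levels (Ho, He,
MAF spectra) therefore track the Balding–Nichols model, not any particular
array.

## Problem sizes and numerical choices

Tests run the full pipeline at genome scale 0.015–0.02 (~40–54 Mb, ~2,000
SNPs, 660 samples), the sweep-recovery property at 20 × 50 Mb with 50 k SNPs,
and null calibrations at 10–20 k SNPs; the acceptance script recomputes all
headline quantities in under a minute on one CPU.  Ties in top-k selection
break by genomic order for determinism; percentile 100 calls nothing; a
single seed drives every stochastic stage through per-stage seeds derived by
stable hashing, so disabling one stage never perturbs another and reruns are
bit-identical (the run manifest carries a content hash that excludes the
output directory path).
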