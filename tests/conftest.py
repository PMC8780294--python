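import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from sweepscope.genotype_io import GenomeLayout, GenotypePanel
from sweepscope.synthetic_data import make_paper_like_scenario, simulate_panel


def build_panel(
    dosages,
    breeds,
    positions=None,
    chroms=None,
    seq_lengths=None,
):
    """Construct a small panel by hand.

    ``dosages`` is (samples x SNPs); ``breeds`` one label per sample;
    positions default to 10 kb spacing on a single chromosome "chr1".
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if positions is None:
        positions = [10_000 * (j + 1) for j in range(m)]
    if chroms is None:
        chroms = ["chr1"] * m
    if seq_lengths is None:
        seq_lengths = {}
        for c, p in zip(chroms, positions):
            seq_lengths[c] = max(seq_lengths.get(c, 0), p + 100_000)
    samples = [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": chroms,
            "pos": positions,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    return GenotypePanel(
        dosages=dosages,
        samples=samples,
        variants=variants,
        breed_of={s: b for s, b in zip(samples, breeds)},
        layout=GenomeLayout(lengths=seq_lengths),
    )


@pytest.fixture(scope="session")
def paper_like_panel():
    """One small study-shaped panel (15 breeds, 660 samples) shared by tests."""
    scenario = make_paper_like_scenario(scale=0.02, seed=11)
    return simulate_panel(scenario)
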