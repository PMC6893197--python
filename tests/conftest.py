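import numpy as np
import pandas as pd
import pytest

from modscreen.synthetic_data import SimulationConfig, simulate_screen
from modscreen.types import GeneAnnotation, PanelGenotypes


@pytest.fixture(scope="session")
def small_cfg():
    """A fast panel: 60 lines x 600 variants, 40 genes, 12 sets."""
    return SimulationConfig(n_lines=60, n_variants=600, n_blocks=6,
                            n_genes=40, chrom_length=500_000, n_sets=12,
                            set_size_range=(4, 12), planted_set_size=6,
                            n_causal=4, seed=11)


@pytest.fixture(scope="session")
def small_screen(small_cfg):
    return simulate_screen(small_cfg)


def make_panel(calls, chrom="2L", start_pos=100, alt_counts=None):
    """Build a PanelGenotypes from a raw (lines x variants) array."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    alt_counts = alt_counts or [1] * m
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom,
        "pos": [start_pos + 10 * j for j in range(m)],
        "ref": "A",
        "alt": [["G"] + ["T"] * (alt_counts[j] - 1) for j in range(m)],
    })
    return PanelGenotypes([f"L{i}" for i in range(n)], variants, calls)


def make_gene(gene_id="gA", chrom="2L", start=1000, end=2000, strand="+",
              exons=None, utrs=None):
    return GeneAnnotation(gene_id, chrom, start, end, strand,
                          exons if exons is not None else [(start, end)],
                          utrs or [])


@pytest.fixture
def make_panel_fx():
    return make_panel


@pytest.fixture
def make_gene_fx():
    return make_gene
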