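"""Shared fixtures: a small synthetic dataset reused across module tests."""

import numpy as np
import pandas as pd
import pytest

from ernascape.io_core import GenomeLayout
from ernascape.synthetic_data import (
    SimConfig,
    simulate_genome,
    simulate_nascent_reads,
    simulate_regulatory_landscape,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        seed=1,
        chrom_length=2_000_000,
        n_triads=30,
        n_enhancers=40,
        n_masked_units=3,
        n_free_units=4,
        frac_expansion_tier=0.0,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    genome = simulate_genome(small_cfg)
    landscape = simulate_regulatory_landscape(small_cfg, genome)
    reads = simulate_nascent_reads(small_cfg, genome, landscape)
    return small_cfg, genome, landscape, reads


@pytest.fixture
def tiny_layout():
    return GenomeLayout({"chr1A": 100_000}, {"chr1A": "A"})


def events_frame(rows):
    """Build a BED6-style events frame from (chrom, pos, strand) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "strand"])
    df["end"] = df["start"] + 1
    df["name"] = "."
    df["score"] = 0
    return df[["chrom", "start", "end", "name", "score", "strand"]]


def random_events(rng, layout, n):
    chroms = rng.choice(layout.chroms, size=n)
    pos = np.array([rng.integers(0, layout.lengths[c]) for c in chroms])
    strands = rng.choice(["+", "-"], size=n)
    return events_frame(list(zip(chroms, pos, strands)))
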