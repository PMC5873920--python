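from __future__ import annotations

import numpy as np
import pytest

from sweepscan.genomic_data import HaplotypeMatrix


def make_matrix(
    states,
    positions=None,
    pops=None,
    polarity=None,
    region_start=1,
    region_end=None,
    chrom="chr1",
) -> HaplotypeMatrix:
    """Build a HaplotypeMatrix from a raw state array with sane defaults."""
    states = np.asarray(states, dtype=np.uint8)
    n, s = states.shape
    if positions is None:
        positions = np.arange(1, s + 1)
    if polarity is None:
        polarity = np.ones(s, dtype=bool)
    if pops is None:
        pops = ["AFR"] * n
    sample_ids = [f"S{i // 2:04d}" for i in range(n)]
    return HaplotypeMatrix(
        states=states,
        positions=np.asarray(positions),
        chrom=chrom,
        polarity=np.asarray(polarity, dtype=bool),
        sample_ids=sample_ids,
        pop_labels=list(pops),
        region_start=region_start,
        region_end=region_end,
    )


def random_matrix(rng, n_haps=None, n_sites=None, pops=("AFR",)) -> HaplotypeMatrix:
    """Random small fixture with at least one segregating configuration."""
    if n_haps is None:
        n_haps = 2 * int(rng.integers(2, 6))
    if n_sites is None:
        n_sites = int(rng.integers(1, 11))
    states = rng.integers(0, 2, size=(n_haps, n_sites)).astype(np.uint8)
    labels = [pops[i % len(pops)] for i in range(n_haps // 2) for _ in range(2)]
    return make_matrix(states, pops=labels, region_end=n_sites)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
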