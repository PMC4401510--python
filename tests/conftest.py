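"""Shared fixtures: small hand-built and simulated haplotype panels."""

import numpy as np
import pytest

from sweepscan import HaplotypePanel, SimConfig, simulate_neutral_panel


def make_panel(alleles, positions=None, pops=None, chromosome="1", length=None):
    """Build a panel from a 2-D 0/1 array; two rows per synthetic sample."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n, m = alleles.shape
    assert n % 2 == 0
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if pops is None:
        pops = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    samples = tuple((f"s{i // 2}", pops[i]) for i in range(n))
    return HaplotypePanel(
        chromosome=chromosome,
        positions=np.asarray(positions),
        alleles=alleles,
        samples=samples,
        length=length,
    )


@pytest.fixture(scope="session")
def neutral_config():
    return SimConfig(
        n_populations=2,
        haplotypes_per_population=12,
        chromosome_length=1_000_000,
        snp_density=5e-4,
        seed=11,
    )


@pytest.fixture(scope="session")
def neutral_panel(neutral_config):
    return simulate_neutral_panel(neutral_config)
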