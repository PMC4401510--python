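"""Windowed nucleotide diversity (π) per population.

π in a window of length L bp over a population's n haplotypes is

    π = (1 / L) · Σ_sites  n/(n−1) · 2 p̂ (1 − p̂)

which equals the mean pairwise per-site Hamming distance among the
population's haplotypes (an algebraic identity, tested as such). The
denominator is the full window length including invariant sites: the input
panel is assumed to carry all segregating sites of the region. Monomorphic
windows are reported with π = 0. The cumulative average (running mean of π
over windows in genome order) is emitted alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError
from .panel import HaplotypePanel

__all__ = ["window_pi", "cumulative_average", "pairwise_window_pi"]


def _window_bounds(panel: HaplotypePanel, window_size: int) -> np.ndarray:
    length = panel.effective_length()
    return np.arange(0, length, window_size, dtype=np.int64)


def window_pi(
    panel: HaplotypePanel, population: str, window_size: int = 10_000_000
) -> pd.DataFrame:
    """Per-window π for one population, including monomorphic windows.

    Windows tile ``[0, chromosome length)``; the last window may be shorter
    and is normalized by its actual span.
    """
    rows = panel.alleles[panel.rows_for(population)]
    n = rows.shape[0]
    if n < 2:
        raise DomainError(f"population {population!r} needs >= 2 haplotypes")
    if window_size <= 0:
        raise DomainError("window_size must be positive")
    p = rows.mean(axis=0)
    per_site = (n / (n - 1)) * 2.0 * p * (1.0 - p)
    starts = _window_bounds(panel, window_size)
    length = panel.effective_length()
    idx = (panel.positions - 1) // window_size  # position 1..w -> window 0
    sums = np.bincount(idx, weights=per_site, minlength=len(starts))[: len(starts)]
    ends = np.minimum(starts + window_size, length)
    pi = sums / (ends - starts)
    return pd.DataFrame(
        {
            "chromosome": panel.chromosome,
            "start": starts,
            "end": ends,
            "population": population,
            "pi": pi,
            "cumulative_mean": cumulative_average(pi),
        }
    )


def cumulative_average(values) -> np.ndarray:
    """Running mean: k-th output is the mean of the first k inputs."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise DomainError("empty series")
    return np.cumsum(arr) / np.arange(1, arr.size + 1)


def pairwise_window_pi(
    panel: HaplotypePanel,
    population_a: str,
    population_b: str,
    window_size: int = 10_000_000,
) -> pd.DataFrame:
    """Between-population π: mean per-site difference between haplotypes
    drawn one from each population, same window normalization."""
    pa = panel.allele_frequencies(population_a)
    pb = panel.allele_frequencies(population_b)
    per_site = pa * (1.0 - pb) + pb * (1.0 - pa)
    starts = _window_bounds(panel, window_size)
    length = panel.effective_length()
    idx = (panel.positions - 1) // window_size
    sums = np.bincount(idx, weights=per_site, minlength=len(starts))[: len(starts)]
    ends = np.minimum(starts + window_size, length)
    pi = sums / (ends - starts)
    return pd.DataFrame(
        {
            "chromosome": panel.chromosome,
            "start": starts,
            "end": ends,
            "population": f"{population_a}|{population_b}",
            "pi": pi,
            "cumulative_mean": cumulative_average(pi),
        }
    )
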