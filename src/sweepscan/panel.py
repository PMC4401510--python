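"""Core in-memory containers.

The central object is the :class:`HaplotypePanel`: a phased, biallelic 0/1
allele matrix over one chromosome, with one row per haplotype (two per diploid
sample) and one column per segregating site. Every statistic in the package —
EHH/iHH/XP-EHH, windowed nucleotide diversity, IBS distances, the GRM — is a
function of this matrix plus the physical positions and population labels.

Gene annotations (:class:`GeneRecord`, 0-based half-open like BED) and
gene→term annotation tables (:class:`TermTable`) are the other two inputs the
downstream stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, UnknownLabelError

__all__ = ["HaplotypePanel", "GeneRecord", "TermTable"]


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval in 0-based half-open coordinates (BED convention)."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ConfigurationError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.start < 0:
            raise ConfigurationError(f"gene {self.gene_id}: negative start")


@dataclass(frozen=True)
class TermTable:
    """Gene→term annotation: mapping of term id to the set of annotated genes.

    ``background_size`` is the number of annotatable genes (the enrichment
    universe); it must be at least as large as the union of all term gene
    sets.
    """

    terms: Mapping[str, frozenset[str]]
    background_size: int

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigurationError("term table has no terms")
        union: set[str] = set()
        for term_id, genes in self.terms.items():
            if not genes:
                raise ConfigurationError(f"term {term_id} annotates no genes")
            union |= set(genes)
        if self.background_size < len(union):
            raise ConfigurationError(
                f"background_size ({self.background_size}) smaller than the "
                f"union of term gene sets ({len(union)})"
            )

    @property
    def universe(self) -> frozenset[str]:
        """All genes annotated to at least one term."""
        out: set[str] = set()
        for genes in self.terms.values():
            out |= set(genes)
        return frozenset(out)


@dataclass(frozen=True)
class HaplotypePanel:
    """Phased haplotypes over one chromosome.

    Parameters
    ----------
    chromosome
        Chromosome label.
    positions
        Strictly increasing 1-based physical positions (bp), one per site.
    alleles
        uint8 matrix of shape ``(n_haplotypes, n_sites)`` with values in
        {0, 1}; row order is file/sample order and is never permuted.
    samples
        One ``(sample_id, population)`` pair per haplotype row; diploid
        samples contribute two consecutive rows.
    length
        Optional chromosome length in bp (defaults to the last position when
        a tiling is needed and no length is known).
    """

    chromosome: str
    positions: np.ndarray
    alleles: np.ndarray
    samples: tuple[tuple[str, str], ...]
    length: int | None = None

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "alleles", alleles)
        if alleles.ndim != 2:
            raise ConfigurationError("allele matrix must be 2-D")
        if alleles.shape != (len(self.samples), len(positions)):
            raise ConfigurationError(
                f"allele matrix shape {alleles.shape} does not match "
                f"{len(self.samples)} haplotypes x {len(positions)} sites"
            )
        if len(positions) and not np.all(np.diff(positions) > 0):
            raise ConfigurationError("positions must be strictly increasing")
        if len(positions) and positions[0] < 1:
            raise ConfigurationError("positions are 1-based; found position < 1")
        if alleles.size and alleles.max() > 1:
            raise ConfigurationError("alleles must be coded 0/1")
        counts: dict[str, int] = {}
        for _, pop in self.samples:
            counts[pop] = counts.get(pop, 0) + 1
        for pop, c in counts.items():
            if c < 2:
                raise ConfigurationError(
                    f"population {pop!r} has {c} haplotype(s); at least 2 required"
                )
        if self.length is not None and len(positions) and self.length < positions[-1]:
            raise ConfigurationError("chromosome length smaller than last position")

    # -- basic geometry -------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> tuple[str, ...]:
        """Population labels in order of first appearance."""
        seen: list[str] = []
        for _, pop in self.samples:
            if pop not in seen:
                seen.append(pop)
        return tuple(seen)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        """Distinct sample ids in order of first appearance."""
        seen: list[str] = []
        for sid, _ in self.samples:
            if sid not in seen:
                seen.append(sid)
        return tuple(seen)

    def rows_for(self, population: str) -> np.ndarray:
        """Row indices of a population's haplotypes, in file order."""
        idx = np.array(
            [i for i, (_, pop) in enumerate(self.samples) if pop == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise UnknownLabelError(f"unknown population {population!r}")
        return idx

    def effective_length(self) -> int:
        if self.length is not None:
            return self.length
        if self.n_sites == 0:
            raise DomainError("panel has no sites and no declared length")
        return int(self.positions[-1])

    # -- derived views --------------------------------------------------
    def allele_frequencies(self, population: str | None = None) -> np.ndarray:
        """Per-site derived-allele frequency, pooled or within a population."""
        rows = self.alleles if population is None else self.alleles[self.rows_for(population)]
        if rows.shape[0] == 0:
            raise DomainError("no haplotypes")
        return rows.mean(axis=0)

    def dosage_matrix(self) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
        """Collapse haplotype pairs to per-sample allele dosages in {0,1,2}.

        Returns ``(sample_ids, sample_populations, dosages)`` with one dosage
        row per diploid sample. Requires exactly two haplotype rows per
        sample id.
        """
        rows_by_sample: dict[str, list[int]] = {}
        pop_by_sample: dict[str, str] = {}
        order: list[str] = []
        for i, (sid, pop) in enumerate(self.samples):
            if sid not in rows_by_sample:
                rows_by_sample[sid] = []
                pop_by_sample[sid] = pop
                order.append(sid)
            rows_by_sample[sid].append(i)
        for sid, rows in rows_by_sample.items():
            if len(rows) != 2:
                raise ConfigurationError(
                    f"sample {sid!r} has {len(rows)} haplotype rows; diploids need 2"
                )
        dosages = np.empty((len(order), self.n_sites), dtype=np.int16)
        for j, sid in enumerate(order):
            a, b = rows_by_sample[sid]
            dosages[j] = self.alleles[a].astype(np.int16) + self.alleles[b]
        pops = tuple(pop_by_sample[s] for s in order)
        return tuple(order), pops, dosages

    def equals(self, other: "HaplotypePanel") -> bool:
        """Exact equality of all fields (arrays compared element-wise)."""
        return (
            self.chromosome == other.chromosome
            and self.samples == other.samples
            and self.length == other.length
            and self.positions.shape == other.positions.shape
            and bool(np.all(self.positions == other.positions))
            and self.alleles.shape == other.alleles.shape
            and bool(np.all(self.alleles == other.alleles))
        )


def validate_same_samples(panels: Sequence[HaplotypePanel]) -> None:
    """Multi-chromosome panel lists must share sample order exactly."""
    if not panels:
        return
    first = panels[0].samples
    for p in panels[1:]:
        if p.samples != first:
            raise ConfigurationError(
                f"panel for chromosome {p.chromosome} has a different sample layout"
            )
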