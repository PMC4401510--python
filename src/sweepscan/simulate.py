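"""Synthetic haplotype panels with known neutral and sweep structure.

The generator is deliberately simple and fully deterministic: segregating
sites are placed uniformly along the chromosome, derived-allele counts follow
the neutral-like 1/k frequency spectrum, and alleles are exchangeable across
chromosomes. Population structure and selection are then layered on top:

* :func:`implant_sweep` models a hard selective sweep by copying one donor
  haplotype onto a fraction of a population's chromosomes around a focal
  position, out to per-side exponential recombination breakpoints — the long
  shared haplotypes that XP-EHH is designed to detect.
* :func:`apply_bottleneck` models reduced effective population size by
  rebuilding a population's haplotypes as recombinant mosaics of a few
  founders, which lowers nucleotide diversity and differentiates populations
  from each other.

Gene annotations and gene→term tables are generated alongside so that the
whole pipeline, through to term enrichment, runs without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, UnknownLabelError
from .panel import GeneRecord, HaplotypePanel, TermTable

__all__ = [
    "SimConfig",
    "SweepSpec",
    "BottleneckSpec",
    "simulate_neutral_panel",
    "implant_sweep",
    "apply_bottleneck",
    "simulate_panel",
    "generate_gene_annotation",
    "generate_term_table",
]


@dataclass(frozen=True)
class SweepSpec:
    """A hard sweep: ``frequency`` of the population's chromosomes carry the
    donor haplotype around ``position``, decaying with mean flank ``scale``
    bp (``math.inf`` copies the whole chromosome)."""

    population: str
    position: int
    frequency: float
    scale: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ConfigurationError("sweep frequency must be in [0, 1]")
        if self.scale <= 0:
            raise ConfigurationError("sweep scale must be positive")
        if self.position < 1:
            raise ConfigurationError("sweep position must be >= 1")


@dataclass(frozen=True)
class BottleneckSpec:
    """Founder bottleneck: the population's haplotypes become mosaics of
    ``n_founders`` of its own rows, with exponential segment lengths of mean
    ``segment_scale`` bp."""

    population: str
    n_founders: int
    segment_scale: float = 1_000_000.0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        if self.segment_scale <= 0:
            raise ConfigurationError("segment_scale must be positive")


@dataclass(frozen=True)
class SimConfig:
    n_populations: int
    haplotypes_per_population: int
    chromosome_length: int
    snp_density: float
    sweep_specs: tuple[SweepSpec, ...] = ()
    bottlenecks: tuple[BottleneckSpec, ...] = ()
    seed: int = 0
    chromosome: str = "1"
    population_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ConfigurationError("need at least one population")
        h = self.haplotypes_per_population
        if h < 4 or h % 2 != 0:
            raise ConfigurationError("haplotypes_per_population must be even and >= 4")
        if self.chromosome_length < 10**5:
            raise ConfigurationError("chromosome_length must be >= 1e5 bp")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be positive")
        labels = self.population_labels
        if labels is None:
            labels = tuple(f"P{i + 1}" for i in range(self.n_populations))
            object.__setattr__(self, "population_labels", labels)
        if len(labels) != self.n_populations or len(set(labels)) != len(labels):
            raise ConfigurationError("population_labels must be unique, one per population")
        for spec in self.sweep_specs:
            if spec.population not in labels:
                raise ConfigurationError(f"sweep population {spec.population!r} not simulated")
            if spec.position > self.chromosome_length:
                raise ConfigurationError("sweep position beyond chromosome end")
            if math.isfinite(spec.scale) and spec.scale >= self.chromosome_length:
                raise ConfigurationError(
                    "finite sweep scale must be smaller than the chromosome"
                )
        for b in self.bottlenecks:
            if b.population not in labels:
                raise ConfigurationError(f"bottleneck population {b.population!r} not simulated")
            if b.n_founders > h:
                raise ConfigurationError("n_founders exceeds haplotypes in population")


def simulate_neutral_panel(config: SimConfig) -> HaplotypePanel:
    """Neutral panel: 1/k derived-allele spectrum, exchangeable chromosomes.

    The number of segregating sites is Binomial(L, density); positions are
    drawn uniformly without replacement; at each site the derived-allele
    count k over the pooled sample is drawn with probability proportional to
    1/k (k = 1..n-1) and assigned to k chromosomes chosen uniformly, so every
    site segregates in the pooled sample by construction. Deterministic given
    ``config.seed``.
    """
    if config.sweep_specs or config.bottlenecks:
        raise ConfigurationError(
            "simulate_neutral_panel requires empty sweep/bottleneck specs; "
            "use simulate_panel for the full study"
        )
    rng = np.random.default_rng(config.seed)
    L = config.chromosome_length
    n = config.n_populations * config.haplotypes_per_population
    n_sites = int(rng.binomial(L, min(config.snp_density, 1.0)))
    positions = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1  # 1-based

    ks = np.arange(1, n)
    weights = 1.0 / ks
    weights /= weights.sum()
    counts = rng.choice(ks, size=n_sites, p=weights)

    # choose exactly k carriers per site: rank i.i.d. uniforms per row
    u = rng.random((n_sites, n))
    ranks = u.argsort(axis=1).argsort(axis=1)
    alleles = (ranks < counts[:, None]).T.astype(np.uint8)  # (n_hap, n_sites)

    samples = []
    for pop in config.population_labels:  # type: ignore[union-attr]
        for i in range(config.haplotypes_per_population // 2):
            sid = f"{pop}_{i + 1:02d}"
            samples.append((sid, pop))
            samples.append((sid, pop))
    return HaplotypePanel(
        chromosome=config.chromosome,
        positions=positions,
        alleles=alleles,
        samples=tuple(samples),
        length=L,
    )


def implant_sweep(panel: HaplotypePanel, spec: SweepSpec, seed: int) -> HaplotypePanel:
    """Copy a donor haplotype onto sweep carriers around ``spec.position``.

    One donor row is chosen in the target population; each of the
    population's rows independently becomes a carrier with probability
    ``spec.frequency``. A carrier copies the donor's alleles from the sweep
    position outward until per-side breakpoints drawn from an exponential
    distribution with mean ``spec.scale`` bp; its own alleles are kept
    beyond. Other populations are untouched. Breakpoints are generated as
    ``scale`` times unit-exponential draws, so for a fixed seed a larger
    scale always copies a superset of sites (haplotype homozygosity around
    the sweep is monotone in ``scale``).
    """
    rows = panel.rows_for(spec.population)  # raises UnknownLabelError
    rng = np.random.default_rng(seed)
    donor_row = int(rows[rng.integers(len(rows))])
    carriers = rng.random(len(rows)) < spec.frequency
    unit = rng.exponential(1.0, size=(len(rows), 2))
    flanks = unit * spec.scale  # inf scale -> inf flanks -> whole chromosome

    alleles = panel.alleles.copy()
    donor = panel.alleles[donor_row]
    pos = panel.positions
    for i, row in enumerate(rows):
        if not carriers[i]:
            continue
        lo = spec.position - flanks[i, 0]
        hi = spec.position + flanks[i, 1]
        mask = (pos >= lo) & (pos <= hi)
        alleles[row, mask] = donor[mask]
    return replace(panel, alleles=alleles)


def apply_bottleneck(panel: HaplotypePanel, spec: BottleneckSpec, seed: int) -> HaplotypePanel:
    """Rebuild a population's haplotypes as founder mosaics.

    ``n_founders`` rows of the population are kept as-is; every other row is
    rebuilt as a mosaic of the founders with exponential segment lengths
    (mean ``segment_scale`` bp), emulating drift through a small founding
    population: within-population diversity drops by roughly a factor
    ``1 - 1/n_founders`` and the population drifts away from the others.
    """
    rows = panel.rows_for(spec.population)
    if spec.n_founders > len(rows):
        raise ConfigurationError("n_founders exceeds haplotypes in population")
    rng = np.random.default_rng(seed)
    founders = rng.choice(rows, size=spec.n_founders, replace=False)
    alleles = panel.alleles.copy()
    pos = panel.positions.astype(np.float64)
    L = float(panel.effective_length()) if panel.n_sites else 0.0
    founder_alleles = panel.alleles[founders]
    for row in rows:
        if row in founders:
            continue
        # breakpoints along the chromosome; founder id per segment
        mosaic = np.empty(panel.n_sites, dtype=np.uint8)
        x = 0.0
        while x < L:
            seg_end = x + rng.exponential(spec.segment_scale)
            fid = rng.integers(spec.n_founders)
            mask = (pos > x) & (pos <= seg_end)
            mosaic[mask] = founder_alleles[fid, mask]
            x = seg_end
        alleles[row] = mosaic
    return replace(panel, alleles=alleles)


def simulate_panel(config: SimConfig) -> HaplotypePanel:
    """Full study panel: neutral base, then bottlenecks, then sweeps.

    All child seeds are derived deterministically from ``config.seed``.
    """
    base = simulate_neutral_panel(replace(config, sweep_specs=(), bottlenecks=()))
    panel = base
    for i, b in enumerate(config.bottlenecks):
        child = int(np.random.SeedSequence([config.seed, 500 + i]).generate_state(1)[0] % (2**31))
        panel = apply_bottleneck(panel, b, seed=child)
    for i, spec in enumerate(config.sweep_specs):
        child = int(np.random.SeedSequence([config.seed, 1000 + i]).generate_state(1)[0] % (2**31))
        panel = implant_sweep(panel, spec, seed=child)
    return panel


def generate_gene_annotation(
    chromosome_length: int,
    n_genes: int,
    seed: int,
    chromosome: str = "1",
    min_length: int = 2_000,
    max_length: int = 20_000,
) -> list[GeneRecord]:
    """Non-overlapping gene intervals with stable ids, sorted by start."""
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_length, max_length + 1, size=n_genes)
    total = int(lengths.sum())
    if total > chromosome_length:
        raise ConfigurationError(
            f"{n_genes} genes of total length {total} bp cannot fit in "
            f"{chromosome_length} bp"
        )
    free = chromosome_length - total
    gaps = np.sort(rng.integers(0, free + 1, size=n_genes))
    starts = gaps + np.concatenate(([0], np.cumsum(lengths)[:-1]))
    return [
        GeneRecord(
            gene_id=f"gene{i + 1:04d}",
            chromosome=chromosome,
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
        )
        for i in range(n_genes)
    ]


def generate_term_table(
    genes: list[GeneRecord],
    n_terms: int,
    enriched_term: str,
    target_genes: list[str],
    seed: int,
) -> TermTable:
    """Term table with one implanted enriched term plus random background.

    ``enriched_term`` annotates all ``target_genes`` plus random padding;
    the remaining ``n_terms - 1`` background terms annotate random gene
    subsets. Background size is the full gene list.
    """
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    gene_ids = [g.gene_id for g in genes]
    known = set(gene_ids)
    for g in target_genes:
        if g not in known:
            raise UnknownLabelError(f"target gene {g!r} not in annotation")
    rng = np.random.default_rng(seed)
    terms: dict[str, frozenset[str]] = {}

    padding_pool = [g for g in gene_ids if g not in set(target_genes)]
    n_pad = int(rng.integers(0, max(1, len(gene_ids) // 10) + 1))
    n_pad = min(n_pad, len(padding_pool))
    padding = list(rng.choice(padding_pool, size=n_pad, replace=False)) if n_pad else []
    enriched_set = frozenset(target_genes) | frozenset(str(g) for g in padding)
    if not enriched_set:
        enriched_set = frozenset(rng.choice(gene_ids, size=1))
    terms[enriched_term] = frozenset(enriched_set)

    hi = max(3, len(gene_ids) // 5)
    for t in range(n_terms - 1):
        size = int(rng.integers(1, hi))
        size = min(size, len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        terms[f"T{t + 1:04d}"] = frozenset(str(g) for g in members)
    return TermTable(terms=terms, background_size=len(gene_ids))
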