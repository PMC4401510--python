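"""Reading and writing the pipeline's file formats.

Phased VCF 4.2 (via cyvcf2 for reading), BED4 gene annotations, tab-delimited
sample maps (sample_id, population) and gene→term tables. Reading is
gzip-transparent. VCF positions are 1-based; BED and all internal window
coordinates are 0-based half-open.

The pipeline consumes *phased, complete* genotypes: any unphased or missing
genotype is a hard error rather than being imputed — phasing and imputation
happen upstream (e.g. BEAGLE) and are out of scope here.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError
from .panel import GeneRecord, HaplotypePanel, TermTable, validate_same_samples

logger = logging.getLogger(__name__)

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_gene_bed",
    "write_gene_bed",
    "read_sample_map",
    "write_sample_map",
    "read_term_table",
    "write_term_table",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | Path, sample_map: Mapping[str, str]) -> list[HaplotypePanel]:
    """Read a phased VCF into one :class:`HaplotypePanel` per chromosome.

    Every diploid sample contributes two haplotype rows in file sample
    order. Multiallelic and non-SNP records are skipped (count logged);
    unphased or missing genotypes raise :class:`FormatError` naming the
    offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in sample_map]
    if missing:
        raise ConfigurationError(
            f"samples absent from the sample map: {', '.join(missing)}"
        )
    owners = tuple(
        (sid, sample_map[sid]) for sid in samples for _ in range(2)
    )
    lengths: dict[str, int] = {}
    try:
        lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:  # header without contig lengths
        lengths = {}

    per_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        gts = variant.genotypes  # [[a, b, phased], ...]
        row = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise FormatError(
                    f"missing genotype for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            if not phased:
                raise FormatError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}; phased input required"
                )
            row[2 * i] = a
            row[2 * i + 1] = b
        chrom = per_chrom.setdefault(variant.CHROM, ([], []))
        chrom[0].append(variant.POS)
        chrom[1].append(row)
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)

    panels = []
    for chrom, (positions, rows) in per_chrom.items():
        alleles = np.stack(rows, axis=1) if rows else np.empty((len(owners), 0), np.uint8)
        panels.append(
            HaplotypePanel(
                chromosome=chrom,
                positions=np.asarray(positions, dtype=np.int64),
                alleles=alleles,
                samples=owners,
                length=lengths.get(chrom),
            )
        )
    return panels


def write_phased_vcf(panels: Sequence[HaplotypePanel], path: str | Path) -> None:
    """Write panels as a sorted, phased, biallelic-SNP VCF 4.2 file.

    Records are grouped by chromosome in panel order, positions ascending
    within each chromosome. REF/ALT are placeholders (A/G): the panel only
    retains the 0/1 coding.
    """
    if not panels:
        raise ConfigurationError("no panels to write")
    validate_same_samples(panels)
    sample_ids = panels[0].sample_ids
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for p in panels:
            if p.length is not None:
                fh.write(f"##contig=<ID={p.chromosome},length={p.length}>\n")
            else:
                fh.write(f"##contig=<ID={p.chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for p in panels:
            A = p.alleles
            for j in range(p.n_sites):
                gts = "\t".join(
                    f"{A[2 * i, j]}|{A[2 * i + 1, j]}" for i in range(len(sample_ids))
                )
                fh.write(
                    f"{p.chromosome}\t{p.positions[j]}\t.\tA\tG\t.\t.\t.\tGT\t{gts}\n"
                )


# ---------------------------------------------------------------------------
# BED genes
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> list[GeneRecord]:
    """Read a BED4+ file of gene intervals, validated and sorted."""
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            records.append(GeneRecord(gene_id=name, chromosome=chrom, start=start, end=end))
    records.sort(key=lambda g: (g.chromosome, g.start, g.end))
    return records


def write_gene_bed(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.end)):
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# sample map / term table
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> dict[str, str]:
    """Tab-delimited (sample_id, population) pairs."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: need sample_id<TAB>population")
            if fields[0] in out:
                raise FormatError(f"{path}:{lineno}: duplicate sample {fields[0]!r}")
            out[fields[0]] = fields[1]
    return out


def write_sample_map(panel_or_samples, path: str | Path) -> None:
    """Accepts a HaplotypePanel or an iterable of (sample_id, population)."""
    if isinstance(panel_or_samples, HaplotypePanel):
        pairs = []
        seen = set()
        for sid, pop in panel_or_samples.samples:
            if sid not in seen:
                seen.add(sid)
                pairs.append((sid, pop))
    else:
        pairs = list(panel_or_samples)
    with _open_text(path, "wt") as fh:
        for sid, pop in pairs:
            fh.write(f"{sid}\t{pop}\n")


def read_term_table(path: str | Path, background_size: int | None = None) -> TermTable:
    """Tab-delimited (term_id, gene_id) pairs.

    ``background_size`` defaults to the number of distinct genes in the
    table (whole-annotation background).
    """
    terms: dict[str, set[str]] = {}
    genes: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: need term_id<TAB>gene_id")
            terms.setdefault(fields[0], set()).add(fields[1])
            genes.add(fields[1])
    if not terms:
        raise FormatError(f"{path}: empty term table")
    return TermTable(
        terms={t: frozenset(g) for t, g in sorted(terms.items())},
        background_size=background_size if background_size is not None else len(genes),
    )


def write_term_table(table: TermTable, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for term_id in sorted(table.terms):
            for gene in sorted(table.terms[term_id]):
                fh.write(f"{term_id}\t{gene}\n")
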