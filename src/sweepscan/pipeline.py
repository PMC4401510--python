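"""End-to-end pipeline: simulate or load, scan, and report.

A :class:`RunConfig` (usually from a YAML file) names either input files
(phased VCF, sample map, gene BED, term table) or a simulation block, the
focal population and its comparison populations, and the scan parameters.
:func:`run_pipeline` executes the stages in order —

    simulate/load → XP-EHH per comparison → window scan per comparison →
    intersection → gene association → enrichment → nucleotide diversity →
    IBS/NJ tree → GRM/PCA

— writing one tab-delimited table per stage plus a JSON manifest (config
echo, seed, per-stage row counts, exclusion counts). Reruns with identical
config and inputs are byte-for-byte identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import ehh, enrichment, hapio, popstruct, windows
from .errors import ConfigurationError, SweepscanError
from .panel import HaplotypePanel, TermTable
from .simulate import (
    BottleneckSpec,
    SimConfig,
    SweepSpec,
    generate_gene_annotation,
    generate_term_table,
    simulate_panel,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "default_study_config"]


@dataclass
class RunConfig:
    focal_population: str
    comparison_populations: tuple[str, ...]
    output_dir: str
    # file-input mode
    vcf: str | None = None
    sample_map: str | None = None
    gene_bed: str | None = None
    term_table: str | None = None
    # simulation mode
    simulation: dict | None = None
    # scan parameters (defaults follow the published procedure)
    window_size: int = 50_000
    cluster_increment: int = 350
    p_cutoff: float = 0.01
    truncation_threshold: float = 0.05
    max_extension: float = 1_000_000.0
    ease_cutoff: float = 0.05
    diversity_window: int = 10_000_000
    pca_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.comparison_populations = tuple(self.comparison_populations)
        if self.focal_population in self.comparison_populations:
            raise ConfigurationError("focal population cannot also be a comparison population")
        if not self.comparison_populations:
            raise ConfigurationError("need at least one comparison population")
        has_files = self.vcf is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ConfigurationError("provide either input files or a simulation block")
        if has_files and self.sample_map is None:
            raise ConfigurationError("file input requires a sample map")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc


def _sim_config_from_block(block: Mapping[str, Any], seed: int) -> SimConfig:
    sweeps = tuple(SweepSpec(**s) for s in block.get("sweeps", []))
    bottlenecks = tuple(BottleneckSpec(**b) for b in block.get("bottlenecks", []))
    return SimConfig(
        n_populations=block["n_populations"],
        haplotypes_per_population=block["haplotypes_per_population"],
        chromosome_length=block["chromosome_length"],
        snp_density=block["snp_density"],
        sweep_specs=sweeps,
        bottlenecks=bottlenecks,
        seed=block.get("seed", seed),
        chromosome=str(block.get("chromosome", "1")),
        population_labels=tuple(block["population_labels"])
        if "population_labels" in block
        else None,
    )


def default_study_config(
    output_dir: str,
    seed: int = 0,
    chromosome_length: int = 75_000_000,
    snp_density: float = 1e-3,
    haplotypes_per_population: int = 24,
) -> RunConfig:
    """The default synthetic five-breed study.

    One focal minipig-like breed compared against three commercial breeds,
    plus an outgroup wild population used only for diversity and structure.
    The focal breed carries the strongest founder bottleneck (lowest π) and
    two implanted hard sweeps; the outgroup has the weakest bottleneck
    (highest π). Sweeps sit mid-window. The chromosome is long enough that
    the within-cluster p < 0.01 cut admits several windows per comparison,
    as in a genome-wide scan.
    """
    L = chromosome_length
    w = 50_000

    def mid_window(pos: int) -> int:
        return (pos // w) * w + w // 2

    sim = {
        "n_populations": 5,
        "haplotypes_per_population": haplotypes_per_population,
        "chromosome_length": L,
        "snp_density": snp_density,
        "population_labels": ["minipig", "breedA", "breedB", "breedC", "wild"],
        "bottlenecks": [
            {"population": "minipig", "n_founders": 8, "segment_scale": 100_000.0},
            {"population": "breedA", "n_founders": 12, "segment_scale": 100_000.0},
            {"population": "breedB", "n_founders": 12, "segment_scale": 100_000.0},
            {"population": "breedC", "n_founders": 12, "segment_scale": 100_000.0},
            {"population": "wild", "n_founders": 16, "segment_scale": 100_000.0},
        ],
        "sweeps": [
            {"population": "minipig", "position": mid_window(L // 4), "frequency": 0.9, "scale": 200_000.0},
            {"population": "minipig", "position": mid_window((3 * L) // 4), "frequency": 0.9, "scale": 200_000.0},
        ],
        "seed": seed,
    }
    return RunConfig(
        focal_population="minipig",
        comparison_populations=("breedA", "breedB", "breedC"),
        output_dir=output_dir,
        simulation=sim,
        seed=seed,
    )


def load_inputs(config: RunConfig):
    """Materialize the run's inputs: simulate them (simulation mode) or read
    them from the configured files. Returns ``(panels, genes, terms)``."""
    if config.simulation is not None:
        sim = _sim_config_from_block(config.simulation, config.seed)
        panel = simulate_panel(sim)
        panels = [panel]
        ann_seed = int(np.random.SeedSequence([sim.seed, 7001]).generate_state(1)[0] % (2**31))
        term_seed = int(np.random.SeedSequence([sim.seed, 7002]).generate_state(1)[0] % (2**31))
        n_genes = max(10, sim.chromosome_length // 50_000)
        genes = generate_gene_annotation(
            sim.chromosome_length, int(n_genes), seed=ann_seed, chromosome=sim.chromosome
        )
        # the implanted enriched term collects the genes around the sweeps
        # (a sweep region spans several genes, like a real swept locus)
        targets = []
        for spec in sim.sweep_specs:
            for g in genes:
                near = g.start < spec.position + 100_000 and g.end > spec.position - 100_000
                if near and g.gene_id not in targets:
                    targets.append(g.gene_id)
        if not targets and genes:
            targets = [genes[0].gene_id]
        terms = generate_term_table(
            genes, n_terms=30, enriched_term="T_SWEEP", target_genes=targets, seed=term_seed
        )
        return panels, genes, terms
    sample_map = hapio.read_sample_map(config.sample_map)
    panels = hapio.read_phased_vcf(config.vcf, sample_map)
    genes = hapio.read_gene_bed(config.gene_bed) if config.gene_bed else []
    terms = hapio.read_term_table(config.term_table) if config.term_table else None
    return panels, genes, terms


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SweepscanError):
                exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _ctx()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifacts; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
    }

    with _stage("load"):
        panels, genes, terms = load_inputs(config)
        lengths = {p.chromosome: p.effective_length() for p in panels}
        all_pops = panels[0].populations
        for pop in (config.focal_population, *config.comparison_populations):
            if pop not in all_pops:
                raise ConfigurationError(f"population {pop!r} not present in the data")
        manifest["stages"]["load"] = {
            "chromosomes": len(panels),
            "sites": int(sum(p.n_sites for p in panels)),
            "haplotypes": panels[0].n_haplotypes,
        }
        if config.simulation is not None:
            hapio.write_phased_vcf(panels, out / "panel.vcf")
            hapio.write_sample_map(panels[0], out / "samples.tsv")
            hapio.write_gene_bed(genes, out / "genes.bed")
            if terms is not None:
                hapio.write_term_table(terms, out / "terms.tsv")

    per_comp_outliers: dict[str, pd.DataFrame] = {}
    outlier_genes: dict[str, list[str]] = {}
    for comp in config.comparison_populations:
        with _stage(f"xpehh:{comp}"):
            parts = []
            excl = {"monomorphic_cores": 0, "zero_ihh": 0, "no_flanking_points": 0}
            for panel in panels:
                df = ehh.xpehh_raw(
                    panel,
                    (config.focal_population, comp),
                    truncation_threshold=config.truncation_threshold,
                    max_extension=config.max_extension,
                )
                for k in excl:
                    excl[k] += df.attrs["exclusions"][k]
                parts.append(df)
            scores = pd.concat(parts, ignore_index=True)
            scores = ehh.standardize_scores(scores)
            _write_tsv(scores, out / f"scores_{comp}.tsv")
            manifest["stages"][f"xpehh:{comp}"] = {
                "scored_cores": int(len(scores)),
                "exclusions": excl,
            }
        with _stage(f"scan:{comp}"):
            win = windows.summarize_windows(scores, lengths, config.window_size)
            win = windows.assign_clusters(win, config.cluster_increment)
            win = windows.empirical_pvalues(win)
            _write_tsv(win, out / f"windows_{comp}.tsv")
            outl = windows.select_outliers(win, config.p_cutoff)
            outl = windows.associate_genes(outl, genes)
            _write_tsv(outl, out / f"outliers_{comp}.tsv")
            per_comp_outliers[comp] = outl
            gene_ids: list[str] = []
            for entry in outl["associated_genes"]:
                for g in str(entry).split(","):
                    if g and g not in gene_ids:
                        gene_ids.append(g)
            outlier_genes[comp] = gene_ids
            manifest["stages"][f"scan:{comp}"] = {
                "windows": int(len(win)),
                "outlier_regions": int(len(outl)),
                "outlier_genes": len(gene_ids),
            }

    with _stage("intersect"):
        table, venn = windows.intersect_outliers(per_comp_outliers)
        _write_tsv(table, out / "intersection.tsv")
        (out / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        manifest["stages"]["intersect"] = {"regions": int(len(table)), "venn": venn}

    if terms is not None:
        for comp in config.comparison_populations:
            with _stage(f"enrich:{comp}"):
                if outlier_genes[comp]:
                    res = enrichment.enrich_terms(outlier_genes[comp], terms, config.ease_cutoff)
                else:
                    res = pd.DataFrame(
                        columns=[
                            "term_id", "list_hits", "list_size", "background_hits",
                            "background_size", "fisher_p", "ease_p", "bh_fdr", "enriched",
                        ]
                    )
                _write_tsv(res, out / f"enrichment_{comp}.tsv")
                manifest["stages"][f"enrich:{comp}"] = {
                    "terms_tested": int(len(res)),
                    "terms_enriched": int(res["enriched"].sum()) if len(res) else 0,
                }

    with _stage("diversity"):
        parts = []
        for pop in all_pops:
            for panel in panels:
                parts.append(div.window_pi(panel, pop, config.diversity_window))
        div_df = pd.concat(parts, ignore_index=True)
        _write_tsv(div_df, out / "diversity.tsv")
        pair_parts = []
        for pop in all_pops:
            if pop == config.focal_population:
                continue
            for panel in panels:
                pair_parts.append(
                    div.pairwise_window_pi(
                        panel, config.focal_population, pop, config.diversity_window
                    )
                )
        _write_tsv(pd.concat(pair_parts, ignore_index=True), out / "diversity_pairwise.tsv")
        manifest["stages"]["diversity"] = {"rows": int(len(div_df))}

    with _stage("tree"):
        ids, pops, dosages = popstruct.dosages_from_panels(panels)
        dm = popstruct.ibs_matrix(dosages, ids)
        pd.DataFrame(dm.data, index=list(ids), columns=list(ids)).to_csv(
            out / "ibs_distance.tsv", sep="\t"
        )
        tree = popstruct.nj_tree(dm)
        (out / "nj_tree.nwk").write_text(str(tree))
        manifest["stages"]["tree"] = {"taxa": len(ids)}

    with _stage("pca"):
        rel = popstruct.grm_pca(dosages, ids, k=config.pca_components)
        frame = rel.to_frame()
        frame["population"] = list(pops)
        _write_tsv(frame, out / "pca_eigenvectors.tsv")
        manifest["stages"]["pca"] = {
            "components": config.pca_components,
            "variance_fractions": [float(f) for f in rel.variance_fractions],
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
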