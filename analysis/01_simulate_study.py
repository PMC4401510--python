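"""Simulate the five-breed study cohort and write its input files.

Builds the default synthetic study — a focal minipig-like breed with two
implanted hard sweeps and a founder bottleneck, three commercial-like
comparison breeds, and a wild outgroup — and writes the phased VCF, sample
map, gene BED and gene→term table under results/data/, plus study.json
recording the design (sweep positions, bottlenecks, comparisons) for the
downstream analysis scripts.
"""

import argparse
import json
from pathlib import Path

from sweepscan import default_study_config, hapio
from sweepscan.pipeline import load_inputs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    config = default_study_config(str(args.out), seed=args.seed)
    panels, genes, terms = load_inputs(config)

    hapio.write_phased_vcf(panels, args.out / "panel.vcf")
    hapio.write_sample_map(panels[0], args.out / "samples.tsv")
    hapio.write_gene_bed(genes, args.out / "genes.bed")
    hapio.write_term_table(terms, args.out / "terms.tsv")
    (args.out / "study.json").write_text(
        json.dumps(
            {
                "focal_population": config.focal_population,
                "comparison_populations": list(config.comparison_populations),
                "simulation": config.simulation,
                "window_size": config.window_size,
                "seed": args.seed,
            },
            indent=2,
        )
        + "\n"
    )

    panel = panels[0]
    sweeps = config.simulation["sweeps"]
    print(f"wrote study inputs to {args.out}")
    print(
        f"  {panel.n_sites} segregating sites on a "
        f"{panel.effective_length() / 1e6:.0f}-Mb chromosome, "
        f"{panel.n_haplotypes} haplotypes in {len(panel.populations)} breeds"
    )
    for s in sweeps:
        print(
            f"  implanted sweep in {s['population']} at {s['position']:,} bp "
            f"(frequency {s['frequency']}, scale {s['scale'] / 1e3:.0f} kb)"
        )
    print(f"  {len(genes)} genes, {len(terms.terms)} GO-like terms "
          f"(implanted enriched term: T_SWEEP)")


if __name__ == "__main__":
    main()
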