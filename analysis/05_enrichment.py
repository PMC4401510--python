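"""EASE-score term enrichment of the outlier gene lists.

For each comparison's outlier genes (from the selection scan) runs the
EASE-modified one-sided Fisher test against the whole-annotation background,
flags terms with EASE < 0.05, and reports pairwise shared-gene Jaccard
distances between the flagged terms. The implanted sweep-region term
(T_SWEEP) is expected to be recovered. Writes results/enrichment/*.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sweepscan import enrich_terms, hapio, term_jaccard

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--scan", type=Path, default=ROOT / "results" / "scan")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "enrichment")
    args = parser.parse_args()

    study = json.loads((args.data / "study.json").read_text())
    comparisons = study["comparison_populations"]
    terms = hapio.read_term_table(args.data / "terms.tsv")
    args.out.mkdir(parents=True, exist_ok=True)

    for comp in comparisons:
        outl = pd.read_csv(args.scan / f"outliers_{comp}.tsv", sep="\t")
        gene_list = sorted(
            {g for e in outl["associated_genes"].dropna() for g in str(e).split(",") if g}
        )
        if not gene_list:
            print(f"{comp}: no outlier genes, skipping")
            continue
        res = enrich_terms(gene_list, terms, cutoff=0.05)
        res.to_csv(args.out / f"enrichment_{comp}.tsv", sep="\t", index=False)
        flagged = res[res["enriched"]]
        print(f"{comp}: {len(gene_list)} outlier genes, "
              f"{len(flagged)} enriched terms of {len(res)} tested")
        for _, row in flagged.iterrows():
            print(
                f"  {row['term_id']:10s} hits {row['list_hits']}/{row['list_size']} "
                f"(background {row['background_hits']}/{row['background_size']}) "
                f"EASE p = {row['ease_p']:.3e}"
            )
        jac = term_jaccard(res, terms)
        if len(jac):
            jac.to_csv(args.out / f"term_jaccard_{comp}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
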