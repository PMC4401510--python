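"""Population structure: IBS distances, NJ tree, GRM-based PCA.

Collapses haplotypes to per-sample allele dosages, computes the 1-IBS
distance matrix and its neighbor-joining tree (checking that every breed is
monophyletic), then the genetic relationship matrix and its leading
eigenvectors with per-component variance fractions. Writes the distance
matrix, Newick tree and eigenvector table under results/structure/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sweepscan import grm_pca, hapio, ibs_matrix, nj_tree
from sweepscan.popstruct import dosages_from_panels

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "structure")
    parser.add_argument("-k", "--components", type=int, default=3)
    args = parser.parse_args()

    sample_map = hapio.read_sample_map(args.data / "samples.tsv")
    panels = hapio.read_phased_vcf(args.data / "panel.vcf", sample_map)
    args.out.mkdir(parents=True, exist_ok=True)

    ids, pops, dosages = dosages_from_panels(panels)
    dm = ibs_matrix(dosages, ids)
    pd.DataFrame(dm.data, index=list(ids), columns=list(ids)).to_csv(
        args.out / "ibs_distance.tsv", sep="\t"
    )
    tree = nj_tree(dm)
    (args.out / "nj_tree.nwk").write_text(str(tree))

    # unrooted monophyly: some edge separates each breed from the rest
    splits = [
        frozenset(t.name for t in node.tips())
        for node in tree.traverse(include_self=False)
        if not node.is_tip()
    ]
    all_tips = frozenset(ids)
    pop_of = dict(zip(ids, pops))
    print(f"neighbor-joining tree over {len(ids)} individuals:")
    for pop in sorted(set(pops)):
        tips = frozenset(i for i in ids if pop_of[i] == pop)
        mono = tips in splits or (all_tips - tips) in splits
        print(f"  {pop:10s} monophyletic: {mono}")

    rel = grm_pca(dosages, ids, k=args.components)
    frame = rel.to_frame()
    frame["population"] = list(pops)
    frame.to_csv(args.out / "pca_eigenvectors.tsv", sep="\t", index=False)
    fractions = ", ".join(
        f"PC{i + 1} {f * 100:.1f}%" for i, f in enumerate(rel.variance_fractions)
    )
    print(f"\nGRM PCA variance fractions: {fractions}")
    pc1 = frame.groupby("population")["PC1"].mean().sort_values()
    print("mean PC1 by breed (separation along the leading axis):")
    for pop, val in pc1.items():
        print(f"  {pop:10s} {val:+.4f}")


if __name__ == "__main__":
    main()
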