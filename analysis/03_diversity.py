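"""Windowed nucleotide diversity (π) per breed.

Computes π in non-overlapping windows for every breed, with the running
(cumulative) average along the chromosome, plus between-breed pairwise π of
the focal breed against every other breed. Writes results/diversity/*.tsv and
prints the genome-wide mean π ranking — the bottlenecked focal breed is
expected lowest, the wild outgroup highest.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sweepscan import hapio, pairwise_window_pi, window_pi

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "diversity")
    parser.add_argument("--window", type=int, default=1_000_000,
                        help="window size in bp")
    args = parser.parse_args()

    study = json.loads((args.data / "study.json").read_text())
    focal = study["focal_population"]
    sample_map = hapio.read_sample_map(args.data / "samples.tsv")
    panels = hapio.read_phased_vcf(args.data / "panel.vcf", sample_map)
    args.out.mkdir(parents=True, exist_ok=True)

    per_pop = pd.concat(
        [window_pi(p, pop, args.window) for p in panels for pop in p.populations],
        ignore_index=True,
    )
    per_pop.to_csv(args.out / "pi_windows.tsv", sep="\t", index=False)

    pairs = pd.concat(
        [
            pairwise_window_pi(p, focal, pop, args.window)
            for p in panels
            for pop in p.populations
            if pop != focal
        ],
        ignore_index=True,
    )
    pairs.to_csv(args.out / "pi_pairwise.tsv", sep="\t", index=False)

    means = per_pop.groupby("population")["pi"].mean().sort_values()
    print(f"genome-wide mean pi by breed ({args.window / 1e6:.0f}-Mb windows):")
    for pop, val in means.items():
        print(f"  {pop:10s} {val:.6e}")
    print(f"lowest diversity: {means.index[0]}"
          + (" (the bottlenecked focal breed, as expected)" if means.index[0] == focal else ""))
    pair_means = pairs.groupby("population")["pi"].mean().sort_values()
    print(f"\nmean pairwise pi of {focal} against the other breeds:")
    for pair, val in pair_means.items():
        print(f"  {pair:20s} {val:.6e}")


if __name__ == "__main__":
    main()
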