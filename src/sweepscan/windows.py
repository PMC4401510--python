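"""Windowed outlier detection for XP-EHH scans.

The genome is tiled with non-overlapping windows (default 50 kb, 0-based
half-open); each window's summary statistic is the *maximum* standardized
XP-EHH of the cores it contains (the statistic is directional, so the maximum
targets selection in population A). To avoid biasing the outlier call toward
SNP-dense windows, windows are stratified into 4 clusters by scored-SNP count
in increments of 350 (1–349, 350–699, 700–1049, ≥1050) and the empirical
p-value of window *i* is the fraction of windows in its cluster whose summary
strictly exceeds it. Windows with p below a cutoff (default 0.01) and a
positive summary are the selected outlier regions; genes overlapping an
outlier window by at least 1 bp are its associated genes, and regions called
in every population comparison form the intersection set.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .panel import GeneRecord

__all__ = [
    "summarize_windows",
    "assign_clusters",
    "empirical_pvalues",
    "select_outliers",
    "associate_genes",
    "intersect_outliers",
]

WINDOW_COLUMNS = ["chromosome", "start", "end", "n_snps", "summary"]


def summarize_windows(
    scores: pd.DataFrame,
    chromosome_lengths: Mapping[str, int] | None = None,
    window_size: int = 50_000,
) -> pd.DataFrame:
    """Per-window scored-core count and maximum standardized score.

    Windows tile ``[0, chromosome length)`` half-open; a position p belongs
    to the window starting at ``(p // window_size) * window_size``. Windows
    containing no scored core are omitted.
    """
    if window_size <= 0:
        raise ConfigurationError("window_size must be positive")
    if "std" not in scores.columns:
        raise ConfigurationError("scores must be standardized first (std column)")
    if chromosome_lengths is not None:
        for chrom, grp in scores.groupby("chromosome", sort=False):
            if chrom not in chromosome_lengths:
                raise ConfigurationError(f"no length for chromosome {chrom!r}")
            if len(grp) and grp["position"].max() > chromosome_lengths[chrom]:
                raise ConfigurationError(f"position beyond chromosome {chrom!r} end")
    df = scores.assign(start=(scores["position"] // window_size) * window_size)
    agg = (
        df.groupby(["chromosome", "start"], sort=False)
        .agg(n_snps=("std", "size"), summary=("std", "max"))
        .reset_index()
    )
    agg["end"] = agg["start"] + window_size
    agg = agg.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
    return agg[WINDOW_COLUMNS]


def assign_clusters(windows: pd.DataFrame, increment: int = 350) -> pd.DataFrame:
    """SNP-count stratification into 4 contiguous clusters.

    With the default increment of 350: cluster 1 holds 1–349 scored SNPs,
    cluster 2 350–699, cluster 3 700–1049, cluster 4 ≥1050.
    """
    if increment <= 0:
        raise ConfigurationError("increment must be positive")
    n = windows["n_snps"].to_numpy()
    if (n < 1).any():
        raise DomainError("windows must contain at least one scored SNP")
    out = windows.copy()
    out["cluster"] = np.minimum(n // increment + 1, 4).astype(int)
    return out


def empirical_pvalues(windows: pd.DataFrame, midrank: bool = False) -> pd.DataFrame:
    """Within-cluster empirical p: fraction of windows strictly greater.

    For window i in a cluster of size N, ``p_i = |{j : summary_j >
    summary_i}| / N`` — the cluster maximum gets exactly 0. With
    ``midrank=True`` the conservative (k+1)/(N+1) variant is used instead.
    """
    if "cluster" not in windows.columns:
        raise ConfigurationError("assign clusters before computing p-values")
    if len(windows) == 0:
        raise DomainError("no windows")
    out = windows.copy()
    grouped = out.groupby("cluster")["summary"]
    n_cluster = grouped.transform("size").to_numpy(dtype=np.float64)
    # ascending max-rank: ties share the highest rank, so N - rank = #greater
    rank_max = grouped.rank(method="max", ascending=True).to_numpy(dtype=np.float64)
    greater = n_cluster - rank_max
    if midrank:
        out["empirical_p"] = (greater + 1.0) / (n_cluster + 1.0)
    else:
        out["empirical_p"] = greater / n_cluster
    return out


def select_outliers(
    windows: pd.DataFrame,
    cutoff: float = 0.01,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Windows with empirical p strictly below ``cutoff``.

    By default only positive summaries qualify: the scan asks for selection
    in population A of the comparison. Set ``positive_only=False`` (after
    negating scores) for the reverse question.
    """
    if "empirical_p" not in windows.columns:
        raise ConfigurationError("compute empirical p-values before selecting outliers")
    mask = windows["empirical_p"] < cutoff
    if positive_only:
        mask &= windows["summary"] > 0
    return windows[mask].reset_index(drop=True)


def associate_genes(outliers: pd.DataFrame, genes: Sequence[GeneRecord]) -> pd.DataFrame:
    """Attach genes overlapping each outlier window by >= 1 bp.

    Both intervals are 0-based half-open, so a gene abutting the window end
    does not qualify. Adds an ``associated_genes`` column (comma-joined,
    empty string when none).
    """
    out = outliers.copy()
    assoc = []
    for _, w in out.iterrows():
        hits = [
            g.gene_id
            for g in genes
            if g.chromosome == w["chromosome"]
            and g.start < w["end"]
            and g.end > w["start"]
        ]
        assoc.append(",".join(hits))
    out["associated_genes"] = assoc
    return out


def intersect_outliers(
    per_comparison: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, dict]:
    """Regions called in every comparison, plus Venn-style counts.

    ``per_comparison`` maps a comparison label to its outlier table (with
    ``associated_genes``). Regions are keyed by (chromosome, start); the
    intersection table carries each comparison's summary and p-value side by
    side. The returned counts dict holds per-comparison totals, pairwise
    overlaps, and the full intersection size.
    """
    if not per_comparison:
        raise DomainError("empty comparison map")
    labels = list(per_comparison)
    sizes = set()
    keysets: dict[str, set] = {}
    for label, df in per_comparison.items():
        if len(df):
            sizes.update((df["end"] - df["start"]).unique().tolist())
        keysets[label] = set(zip(df["chromosome"], df["start"]))
    if len(sizes) > 1:
        raise ConfigurationError(f"mismatched window grids: sizes {sorted(sizes)}")

    common = set.intersection(*keysets.values())
    counts: dict = {
        "per_comparison": {lab: len(keysets[lab]) for lab in labels},
        "pairwise": {
            f"{a}&{b}": len(keysets[a] & keysets[b])
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
        },
        "intersection": len(common),
    }

    rows = []
    first = labels[0]
    indexed = {
        lab: df.set_index(["chromosome", "start"]) for lab, df in per_comparison.items()
    }
    for key in sorted(common, key=lambda k: (str(k[0]), k[1])):
        base = indexed[first].loc[key]
        row = {
            "chromosome": key[0],
            "start": key[1],
            "end": int(base["end"]),
            "n_snps": int(base["n_snps"]),
        }
        genes: list[str] = []
        for lab in labels:
            rec = indexed[lab].loc[key]
            row[f"xpehh_{lab}"] = float(rec["summary"])
            row[f"p_{lab}"] = float(rec["empirical_p"])
            if "associated_genes" in rec.index and rec["associated_genes"]:
                for g in str(rec["associated_genes"]).split(","):
                    if g and g not in genes:
                        genes.append(g)
        row["associated_genes"] = ",".join(genes)
        rows.append(row)
    columns = ["chromosome", "start", "end", "n_snps"]
    for lab in labels:
        columns += [f"xpehh_{lab}", f"p_{lab}"]
    columns.append("associated_genes")
    table = pd.DataFrame(rows, columns=columns)
    return table, counts
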