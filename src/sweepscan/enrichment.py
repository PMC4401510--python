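"""EASE-score term enrichment for outlier gene lists.

The EASE score is a conservative variant of the one-sided Fisher exact test
popularized by the DAVID toolchain: before computing the hypergeometric upper
tail, one gene is removed from the list/term overlap. With a list of size s
from a background of size N, a term annotating K background genes, and k list
genes hitting the term:

    fisher_p = P(X >= k)      X ~ Hypergeom(N, K, s)
    ease_p   = P(X >= k − 1)  (and 1 when k <= 1)

so ease_p >= fisher_p whenever the term is hit at all. Terms with
ease_p below a cutoff (default 0.05) are flagged enriched. A
Benjamini–Hochberg FDR column is emitted for information only; the selection
itself uses the raw EASE score.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DomainError
from .panel import TermTable

__all__ = ["ease_score", "enrich_terms", "term_jaccard"]


def ease_score(
    list_hits: int, list_size: int, background_hits: int, background_size: int
) -> tuple[float, float]:
    """(fisher_p, ease_p) for one 2x2 table, both hypergeometric upper tails."""
    if not (
        0 <= list_hits <= min(list_size, background_hits)
        and 0 < list_size <= background_size
        and 0 <= background_hits <= background_size
        and list_size - list_hits <= background_size - background_hits
    ):
        raise DomainError(
            f"inconsistent counts: hits {list_hits}/{list_size} vs "
            f"{background_hits}/{background_size}"
        )
    fisher_p = float(hypergeom.sf(list_hits - 1, background_size, background_hits, list_size))
    if list_hits <= 1:
        ease_p = 1.0
    else:
        ease_p = float(hypergeom.sf(list_hits - 2, background_size, background_hits, list_size))
    return min(fisher_p, 1.0), min(ease_p, 1.0)


def enrich_terms(
    gene_list: Iterable[str], terms: TermTable, cutoff: float = 0.05
) -> pd.DataFrame:
    """Score every term hit by the gene list against the whole-annotation
    background.

    The effective list is the distinct genes of ``gene_list`` restricted to
    the annotation universe; terms with no list hit are omitted. Results are
    sorted ascending by ``ease_p`` with an ``enriched`` flag at
    ``ease_p < cutoff`` and a BH-FDR column over the tested terms.
    """
    genes = set(gene_list)
    if not genes:
        raise DomainError("empty gene list")
    universe = terms.universe
    listed = genes & universe
    rows = []
    for term_id in sorted(terms.terms):
        members = terms.terms[term_id]
        hits = listed & set(members)
        if not hits:
            continue
        fisher_p, ease_p = ease_score(
            len(hits), max(len(listed), 1), len(members), terms.background_size
        )
        rows.append(
            {
                "term_id": term_id,
                "list_hits": len(hits),
                "list_size": len(listed),
                "background_hits": len(members),
                "background_size": terms.background_size,
                "fisher_p": fisher_p,
                "ease_p": ease_p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "list_hits",
            "list_size",
            "background_hits",
            "background_size",
            "fisher_p",
            "ease_p",
        ],
    )
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["bh_fdr"] = multipletests(df["ease_p"], method="fdr_bh")[1]
        df["enriched"] = df["ease_p"] < cutoff
        df = df.sort_values(["ease_p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["bh_fdr"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df


def term_jaccard(results: pd.DataFrame, terms: TermTable) -> pd.DataFrame:
    """Pairwise shared-gene Jaccard distance between enriched terms.

    A flat report of how much the flagged terms' gene lists overlap (the
    ingredient of a term-clustering view); distance 0 means identical gene
    sets.
    """
    flagged = [t for t in results.loc[results["enriched"], "term_id"]]
    rows = []
    for i, a in enumerate(flagged):
        for b in flagged[i + 1 :]:
            ga, gb = set(terms.terms[a]), set(terms.terms[b])
            jaccard = len(ga & gb) / len(ga | gb)
            rows.append({"term_a": a, "term_b": b, "jaccard_distance": 1.0 - jaccard})
    return pd.DataFrame(rows, columns=["term_a", "term_b", "jaccard_distance"])
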