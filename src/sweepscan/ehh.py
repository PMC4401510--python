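"""Extended haplotype homozygosity, iHH integration and XP-EHH scores.

For a core SNP, EHH at a flanking SNP is the probability that two haplotypes
drawn at random (without replacement) from the sample are identical over the
whole interval from the core to that SNP inclusive:

    EHH = sum_h C(c_h, 2) / C(n, 2)

with c_h the multiplicities of distinct haplotypes over the interval. The
curve starts at (0, 1) by convention and is non-increasing with distance,
since adding sites can only split haplotype classes.

iHH is the area under the EHH decay curve (trapezoidal rule over physical
distance in bp), summed over the two flanks. The cross-population score at a
core SNP is

    XP-EHH = ln(iHH_A / iHH_B)

where both integrals run over the *same* interval, truncated where the EHH of
the pooled A∪B sample drops below a threshold (default 0.05) — so the ratio
compares identical genomic intervals and any per-bp distance scaling cancels.
Positive values indicate longer haplotype homozygosity (a candidate sweep) in
population A. Raw scores are standardized genome-wide to mean 0, sd 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .panel import HaplotypePanel

__all__ = [
    "EHHCurve",
    "ehh_at_interval",
    "build_ehh_curve",
    "integrate_ihh",
    "xpehh_raw",
    "standardize_scores",
]


def _homozygosity(counts: np.ndarray, n: int) -> float:
    """sum C(c,2) / C(n,2) from class multiplicities."""
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_at_interval(rows: np.ndarray, site_slice: tuple[int, int]) -> float:
    """Haplotype homozygosity of ``rows`` over an inclusive site index range.

    Equals the probability that two distinct rows drawn uniformly are
    identical across the slice.
    """
    rows = np.asarray(rows)
    n = rows.shape[0]
    if n < 2:
        raise DomainError("EHH needs at least 2 haplotypes")
    lo, hi = site_slice
    sub = rows[:, lo : hi + 1]
    _, counts = np.unique(sub, axis=0, return_counts=True)
    return _homozygosity(counts.astype(np.float64), n)


@dataclass
class EHHCurve:
    """EHH decay around one core SNP, one entry per retained flanking point.

    Each side's arrays start at the core with distance 0 and EHH 1 for the
    pooled sample and both populations. ``left``/``right`` hold positive
    distances (bp) from the core; ``*_pooled``/``*_a``/``*_b`` the matching
    EHH values. ``truncated_by_chromosome_end`` flags sides that ran out of
    SNPs before the pooled EHH fell below the threshold.
    """

    core_position: int
    left_dist: np.ndarray
    left_pooled: np.ndarray
    left_a: np.ndarray
    left_b: np.ndarray
    right_dist: np.ndarray
    right_pooled: np.ndarray
    right_a: np.ndarray
    right_b: np.ndarray
    truncated_by_chromosome_end: tuple[bool, bool] = (False, False)

    def side(self, which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if which == "left":
            return self.left_dist, self.left_pooled, self.left_a, self.left_b
        return self.right_dist, self.right_pooled, self.right_a, self.right_b


def _walk_side(
    alleles: np.ndarray,
    positions: np.ndarray,
    core: int,
    step: int,
    na: int,
    threshold: float,
    max_extension: float,
) -> tuple[list[float], list[float], list[float], list[float], bool]:
    """Extend SNP-by-SNP from the core in direction ``step`` (+1/-1).

    ``alleles`` rows are ordered population A first (na rows) then B. The
    interval always includes the core site. Stops at the first SNP where the
    pooled EHH drops below ``threshold`` (that SNP is retained as terminal
    point), at ``max_extension`` bp, or at the chromosome end.
    """
    n = alleles.shape[0]
    nb = n - na
    dist = [0.0]
    pooled = [1.0]
    ehh_a = [1.0]
    ehh_b = [1.0]
    core_pos = positions[core]

    ids = np.zeros(n, dtype=np.int64)
    # include the core site itself in the interval
    _, ids = np.unique(alleles[:, core], return_inverse=True)
    j = core
    hit_end = True
    while True:
        j += step
        if j < 0 or j >= alleles.shape[1]:
            break
        d = abs(int(positions[j]) - int(core_pos))
        if d > max_extension:
            hit_end = False
            break
        ids = ids * 2 + alleles[:, j]
        _, ids = np.unique(ids, return_inverse=True)
        counts = np.bincount(ids).astype(np.float64)
        e_pool = _homozygosity(counts, n)
        ca = np.bincount(ids[:na]).astype(np.float64)
        cb = np.bincount(ids[na:]).astype(np.float64)
        dist.append(float(d))
        pooled.append(e_pool)
        ehh_a.append(_homozygosity(ca, na))
        ehh_b.append(_homozygosity(cb, nb))
        if e_pool < threshold:
            hit_end = False
            break
    return dist, pooled, ehh_a, ehh_b, hit_end


def build_ehh_curve(
    panel: HaplotypePanel,
    populations: tuple[str, str],
    core_index: int,
    truncation_threshold: float = 0.05,
    max_extension: float = 1_000_000.0,
) -> EHHCurve | None:
    """EHH decay curve around one core SNP for a population pair.

    Returns ``None`` when the core is monomorphic in the pooled A∪B sample
    (a skip signal, not an error). The truncation boundary is set by the
    *pooled* sample's EHH so both populations are integrated over the same
    interval.
    """
    pop_a, pop_b = populations
    rows_a = panel.rows_for(pop_a)
    rows_b = panel.rows_for(pop_b)
    sub = panel.alleles[np.concatenate([rows_a, rows_b])]
    col = sub[:, core_index]
    if col.min() == col.max():
        return None
    na = len(rows_a)
    ld, lp, la, lb, l_end = _walk_side(
        sub, panel.positions, core_index, -1, na, truncation_threshold, max_extension
    )
    rd, rp, ra, rb, r_end = _walk_side(
        sub, panel.positions, core_index, +1, na, truncation_threshold, max_extension
    )
    return EHHCurve(
        core_position=int(panel.positions[core_index]),
        left_dist=np.asarray(ld),
        left_pooled=np.asarray(lp),
        left_a=np.asarray(la),
        left_b=np.asarray(lb),
        right_dist=np.asarray(rd),
        right_pooled=np.asarray(rp),
        right_a=np.asarray(ra),
        right_b=np.asarray(rb),
        truncated_by_chromosome_end=(l_end, r_end),
    )


def integrate_ihh(curve_side: tuple[np.ndarray, np.ndarray] | list) -> float:
    """Trapezoidal area under one side of an EHH curve.

    ``curve_side`` is ``(distances, ehh_values)`` (or a sequence of
    ``(distance, ehh)`` pairs) sorted by distance, starting at ``(0, 1)``.
    A side holding only the core point contributes 0.
    """
    if isinstance(curve_side, tuple) and len(curve_side) == 2 and np.ndim(curve_side[0]) == 1:
        dist = np.asarray(curve_side[0], dtype=np.float64)
        ehh = np.asarray(curve_side[1], dtype=np.float64)
    else:
        arr = np.asarray(curve_side, dtype=np.float64)
        dist, ehh = arr[:, 0], arr[:, 1]
    if dist.size == 0 or dist[0] != 0 or ehh[0] != 1:
        raise DomainError("curve side must start at (0, 1)")
    if dist.size < 2:
        return 0.0
    return float(np.trapezoid(ehh, dist))


def site_ihh(curve: EHHCurve) -> tuple[float, float, bool]:
    """(iHH_A, iHH_B, defined) for a curve, using the pooled truncation.

    ``defined`` is False when both sides hold only the core point (no
    flanking SNP before truncation), in which case the core is excluded.
    """
    if len(curve.left_dist) < 2 and len(curve.right_dist) < 2:
        return 0.0, 0.0, False
    ihh_a = integrate_ihh((curve.left_dist, curve.left_a)) + integrate_ihh(
        (curve.right_dist, curve.right_a)
    )
    ihh_b = integrate_ihh((curve.left_dist, curve.left_b)) + integrate_ihh(
        (curve.right_dist, curve.right_b)
    )
    return ihh_a, ihh_b, True


def xpehh_raw(
    panel: HaplotypePanel,
    populations: tuple[str, str],
    truncation_threshold: float = 0.05,
    max_extension: float = 1_000_000.0,
) -> pd.DataFrame:
    """Raw XP-EHH scores for every eligible core SNP of one chromosome.

    Returns a DataFrame with columns ``chromosome, position, ihh_a, ihh_b,
    raw``; exclusion counts (monomorphic cores, zero iHH, no flanking
    points) are attached under ``df.attrs["exclusions"]``.
    """
    pop_a, pop_b = populations
    rows_a = panel.rows_for(pop_a)
    rows_b = panel.rows_for(pop_b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise DomainError("both populations need at least 2 haplotypes")
    sub = panel.alleles[np.concatenate([rows_a, rows_b])]
    na = len(rows_a)

    positions = []
    ihh_as = []
    ihh_bs = []
    n_mono = n_zero = n_noflank = 0
    colsum = sub.sum(axis=0)
    n_pool = sub.shape[0]
    for core in range(panel.n_sites):
        if colsum[core] == 0 or colsum[core] == n_pool:
            n_mono += 1
            continue
        ld, lp, la, lb, _ = _walk_side(
            sub, panel.positions, core, -1, na, truncation_threshold, max_extension
        )
        rd, rp, ra, rb, _ = _walk_side(
            sub, panel.positions, core, +1, na, truncation_threshold, max_extension
        )
        if len(ld) < 2 and len(rd) < 2:
            n_noflank += 1
            continue
        ihh_a = integrate_ihh((np.asarray(ld), np.asarray(la))) + integrate_ihh(
            (np.asarray(rd), np.asarray(ra))
        )
        ihh_b = integrate_ihh((np.asarray(ld), np.asarray(lb))) + integrate_ihh(
            (np.asarray(rd), np.asarray(rb))
        )
        if ihh_a == 0.0 or ihh_b == 0.0:
            n_zero += 1
            continue
        positions.append(int(panel.positions[core]))
        ihh_as.append(ihh_a)
        ihh_bs.append(ihh_b)

    df = pd.DataFrame(
        {
            "chromosome": panel.chromosome,
            "position": np.asarray(positions, dtype=np.int64),
            "ihh_a": np.asarray(ihh_as, dtype=np.float64),
            "ihh_b": np.asarray(ihh_bs, dtype=np.float64),
        }
    )
    # log difference, not log of the quotient: keeps antisymmetry bit-exact
    df["raw"] = np.log(df["ihh_a"]) - np.log(df["ihh_b"])
    df.attrs["exclusions"] = {
        "monomorphic_cores": n_mono,
        "zero_ihh": n_zero,
        "no_flanking_points": n_noflank,
    }
    return df


def standardize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Add a ``std`` column: (raw − mean) / sd with sd on n−1 denominator.

    Applied genome-wide across all chromosomes of a comparison (concatenate
    per-chromosome score tables first).
    """
    raw = scores["raw"].to_numpy(dtype=np.float64)
    if raw.size < 2:
        raise DomainError("standardization needs at least 2 scores")
    sd = raw.std(ddof=1)
    if sd == 0.0:
        raise DomainError("all raw scores equal; degenerate distribution")
    out = scores.copy()
    out["std"] = (raw - raw.mean()) / sd
    out.attrs = dict(scores.attrs)
    return out
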