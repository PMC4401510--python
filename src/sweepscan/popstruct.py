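"""Population structure: IBS distances, neighbor-joining tree, GRM and PCA.

Individuals are compared on allele dosages (0/1/2, the sum of a sample's two
haplotype rows). The identity-by-state similarity of two individuals is the
mean over loci of (shared alleles)/2, where a locus contributes 0, 1 or 2
shared alleles; identical individuals score 1 and the distance matrix is
1 − IBS. The neighbor-joining tree (Saitou–Nei) is built from that distance
matrix; NJ is exact on additive matrices. The genetic relationship matrix is
the standard allele-frequency-standardized genotype covariance

    G_ij = (1/m) Σ_l (x_il − 2 p_l)(x_jl − 2 p_l) / (2 p_l (1 − p_l))

over the m polymorphic loci, and PCA is its eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .errors import DomainError
from .panel import HaplotypePanel

__all__ = ["ibs_matrix", "nj_tree", "grm", "grm_pca", "RelationshipMatrix", "dosages_from_panels"]


def dosages_from_panels(panels) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Concatenate per-chromosome dosage matrices (samples x loci)."""
    ids = None
    pops = None
    blocks = []
    for panel in panels:
        i, p, d = panel.dosage_matrix()
        if ids is None:
            ids, pops = i, p
        elif i != ids:
            raise DomainError("panels have different sample layouts")
        blocks.append(d)
    if ids is None:
        raise DomainError("no panels")
    return ids, pops, np.concatenate(blocks, axis=1)


def ibs_matrix(dosages: np.ndarray, labels) -> DistanceMatrix:
    """1 − IBS distance matrix from per-sample dosage vectors.

    Shared alleles at a locus = 2 − |d_i − d_j|, so the distance is the mean
    over loci of |d_i − d_j| / 2; entries lie in [0, 1] with 0 on the
    diagonal and for identical individuals ("twin pairs").
    """
    D = np.asarray(dosages, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] < 2:
        raise DomainError("need a 2-D dosage matrix with >= 2 samples")
    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(D, metric="cityblock") / (2.0 * D.shape[1]))
    return DistanceMatrix(dist, ids=list(labels))


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; exact on additive matrices."""
    if d.shape[0] < 3:
        raise DomainError("neighbor joining needs >= 3 taxa")
    return nj(d)


@dataclass
class RelationshipMatrix:
    """GRM with its top-k eigenpairs and per-component variance fractions."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    eigenvalues: np.ndarray  # descending, length k
    eigenvectors: np.ndarray  # (n_samples, k), orthonormal columns
    variance_fractions: np.ndarray  # eigenvalue / trace-of-positive-part

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.eigenvectors[:, i] for i in range(self.eigenvectors.shape[1])}
        return pd.DataFrame({"sample": list(self.labels), **cols})


def grm(dosages: np.ndarray) -> np.ndarray:
    """Allele-frequency standardized genotype covariance; monomorphic loci dropped."""
    D = np.asarray(dosages, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] < 2:
        raise DomainError("need a 2-D dosage matrix with >= 2 samples")
    p = D.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise DomainError("all loci monomorphic")
    D = D[:, keep]
    p = p[keep]
    W = (D - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return W @ W.T / W.shape[1]


def grm_pca(dosages: np.ndarray, labels, k: int = 2) -> RelationshipMatrix:
    """Top-k eigenpairs of the GRM (EIGENSTRAT-equivalent axes).

    Variance fractions are each eigenvalue over the sum of all eigenvalues
    (reported as in "eigenvector 1 accounted for 19% of the variance").
    """
    labels = tuple(labels)
    G = grm(dosages)
    if k < 1 or k > G.shape[0]:
        raise DomainError(f"k={k} out of range for {G.shape[0]} samples")
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    total = vals.sum()
    fractions = vals[:k] / total if total > 0 else np.full(k, np.nan)
    return RelationshipMatrix(
        labels=labels,
        matrix=G,
        eigenvalues=vals[:k],
        eigenvectors=vecs[:, :k],
        variance_fractions=fractions,
    )
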