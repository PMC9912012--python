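"""Double principal coordinate analysis and weighted UniFrac.

DPCoA embeds the taxa by their phylogenetic distances and places each
sample at the abundance-weighted centroid of its taxa, so that squared
inter-sample distances equal the Rao (DISC) dissimilarity between
compositions:

    ||s_a − s_b||² = d_ab − ½(d_aa + d_bb),   d_xy = Σ_ij f_i^x f_j^y D_ij.

Patristic distances D on a tree are not Euclidean-embeddable in general,
but their square roots are, so the taxon embedding is the classical PCoA
of √D (whose squared point distances restore D). A final abundance-
weighted PCA of the sample cloud orders the axes by explained inertia.

Weighted UniFrac is computed on the branch-incidence matrix:
Σ_b l_b·|A_b − B_b| with A_b the fraction of sample a's abundance below
branch b; the normalized variant divides by Σ_b l_b·(A_b + B_b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .phylo import branch_incidence, patristic_matrix

EIG_TOL = 1e-8


@dataclass
class DPCoAResult:
    taxon_coords: pd.DataFrame
    sample_coords: pd.DataFrame
    eigenvalues: np.ndarray
    axis_variance_fraction: np.ndarray


def dpcoa(counts: pd.DataFrame, tree: TreeNode) -> DPCoAResult:
    """Double principal coordinate analysis of a count table on a tree."""
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every sample must contain at least one count")
    taxa = list(counts.columns)
    D = patristic_matrix(tree, taxa).to_numpy()

    # taxon embedding: PCoA of sqrt(D); squared coordinate distances = D
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D @ J
    G = (G + G.T) / 2.0
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(vals.max(), 1.0)
    if vals.min() < -EIG_TOL * scale:
        raise ValueError(
            "distance matrix is not Euclidean-embeddable after the square-root "
            f"transform (most negative eigenvalue {vals.min():.3e})"
        )
    keep = vals > EIG_TOL * scale
    X = vecs[:, keep] * np.sqrt(vals[keep])

    # samples at abundance-weighted centroids of their taxa
    F = arr / totals[:, None]
    S = F @ X

    # abundance-weighted PCA of the sample cloud to order the axes
    w = totals / totals.sum()
    mu = w @ S
    Sc = S - mu
    C = Sc.T @ (Sc * w[:, None])
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    keep2 = evals > EIG_TOL * max(evals.max(), 1.0)
    evals, R = evals[keep2], evecs[:, keep2]

    sample_coords = Sc @ R
    taxon_coords = (X - mu) @ R
    axes = [f"Axis{i + 1}" for i in range(sample_coords.shape[1])]
    return DPCoAResult(
        taxon_coords=pd.DataFrame(taxon_coords, index=taxa, columns=axes),
        sample_coords=pd.DataFrame(sample_coords, index=counts.index, columns=axes),
        eigenvalues=evals,
        axis_variance_fraction=evals / evals.sum(),
    )


def rao_dissimilarity(abund_a, abund_b, dist: pd.DataFrame) -> float:
    """Rao DISC dissimilarity d_ab − ½(d_aa + d_bb) between two compositions."""
    fa = np.asarray(abund_a, dtype=float)
    fb = np.asarray(abund_b, dtype=float)
    fa, fb = fa / fa.sum(), fb / fb.sum()
    D = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist)
    return float(fa @ D @ fb - 0.5 * (fa @ D @ fa + fb @ D @ fb))


def weighted_unifrac(
    abund_a: pd.Series,
    abund_b: pd.Series,
    tree: TreeNode,
    normalized: bool = False,
) -> float:
    """Weighted UniFrac distance between two samples."""
    taxa = sorted(set(abund_a.index) | set(abund_b.index))
    lengths, incidence = branch_incidence(tree, taxa)
    fa = abund_a.reindex(taxa, fill_value=0).to_numpy(dtype=float)
    fb = abund_b.reindex(taxa, fill_value=0).to_numpy(dtype=float)
    fa, fb = fa / fa.sum(), fb / fb.sum()
    A = incidence @ fa
    B = incidence @ fb
    raw = float(lengths @ np.abs(A - B))
    if not normalized:
        return raw
    denom = float(lengths @ (A + B))
    return raw / denom if denom > 0 else 0.0


def weighted_unifrac_matrix(
    counts: pd.DataFrame, tree: TreeNode, normalized: bool = False
) -> pd.DataFrame:
    """All pairwise weighted UniFrac distances for a count table."""
    taxa = list(counts.columns)
    lengths, incidence = branch_incidence(tree, taxa)
    arr = counts.to_numpy(dtype=float)
    F = arr / arr.sum(axis=1, keepdims=True)
    A = incidence @ F.T  # branches x samples
    s = counts.shape[0]
    out = np.zeros((s, s))
    for i in range(s):
        diff = np.abs(A[:, i : i + 1] - A[:, i + 1 :])
        vals = lengths @ diff
        if normalized:
            denom = lengths @ (A[:, i : i + 1] + A[:, i + 1 :])
            vals = np.divide(vals, denom, out=np.zeros_like(vals), where=denom > 0)
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return pd.DataFrame(out, index=counts.index, columns=counts.index)
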