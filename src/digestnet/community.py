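"""Whole-community analyses on the ASV table.

Low-abundance filtering, relative abundances, Bray-Curtis dissimilarity,
hierarchical clustering, principal-coordinate analysis, PERMANOVA, and the
prevalence-based core-microbiome screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import AbundanceTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "CoreSet",
    "filter_low_abundance",
    "relative_abundance",
    "bray_curtis",
    "hierarchical_cluster",
    "pcoa",
    "permanova",
    "core_microbiome",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarities with zero diagonal."""

    ids: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match id list")
        if not np.allclose(np.diag(m), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        finite = np.isfinite(m)
        if not np.array_equal(m == m, m.T == m.T) or not np.allclose(
            m[finite & finite.T], m.T[finite & finite.T]
        ):
            raise ValidationError("distance matrix must be symmetric")
        if np.nanmin(m) < 0:
            raise ValidationError("distances must be non-negative")
        self.matrix = m

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class CoreSet:
    """ASVs present in at least ``threshold`` of samples."""

    members: list
    threshold: float
    read_fraction: float


def filter_low_abundance(table: AbundanceTable, min_mean: float = 1.0) -> AbundanceTable:
    """Drop ASVs whose mean count across samples falls below ``min_mean``.

    Mirrors the standard pre-filter of removing taxa with less than one
    observation on average across the series.
    """
    means = table.counts.mean(axis=1)
    keep = means[means >= min_mean].index
    if len(keep) == 0:
        raise ValidationError("filter removed every ASV")
    return table.subset_asvs(keep)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1)."""
    sums = counts.sum(axis=0)
    empty = sums[sums <= 0].index.tolist()
    if empty:
        raise ValidationError(f"samples with zero total counts: {empty}")
    return counts / sums


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between columns of ``matrix``.

    ``d(x, y) = sum |x - y| / sum (x + y)``; a pair whose combined
    abundance is all-zero has no defined dissimilarity and is flagged NaN.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative values")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[:, i, None] - x[:, i + 1:]).sum(axis=0)
        tot = (x[:, i, None] + x[:, i + 1:]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), np.nan)
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return DistanceMatrix(list(matrix.columns), d)


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete"):
    """Agglomerative clustering of a distance matrix.

    Returns the scipy linkage matrix (n-1 merges with heights); leaves are
    ordered as ``d.ids``.
    """
    if d.n < 2:
        raise ValidationError("need at least two samples to cluster")
    if linkage not in ("complete", "average", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    return hierarchy.linkage(d.condensed(), method=linkage)


def dendrogram_newick(linkage_matrix: np.ndarray, ids: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage_matrix)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # all of them, negatives included
    variance_fractions: np.ndarray  # eigenvalue / sum of positive eigenvalues


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling.

    Double-centers ``-0.5 * D**2`` and eigendecomposes; axes are ordered by
    decreasing eigenvalue and scaled by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are reported, not dropped; variance
    fractions are taken over the positive eigenvalues only.
    """
    dm = d.matrix
    if np.isnan(dm).any():
        raise ValidationError("PCoA requires a complete distance matrix")
    n = d.n
    a = -0.5 * dm**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frame = pd.DataFrame(
        coords, index=d.ids, columns=[f"PCo{i + 1}" for i in range(pos.sum())]
    )
    fractions = np.where(pos, eigvals / eigvals[pos].sum(), 0.0)
    return OrdinationResult(frame, eigvals, fractions)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and group labels.

    Uses the partitioning of the total sum of squared distances
    ``SST = sum_{i<j} d_ij^2 / n`` into within-group
    ``SSW = sum_g sum_{i<j in g} d_ij^2 / n_g`` and among-group remainder.
    """
    n = len(labels)
    iu = np.triu_indices(n, 1)
    sst = d2[iu].sum() / n
    ssw = 0.0
    groups, counts = np.unique(labels, return_counts=True)
    for g, n_g in zip(groups, counts):
        mask = labels == g
        sub = d2[np.ix_(mask, mask)]
        ssw += sub[np.triu_indices(n_g, 1)].sum() / n_g
    ssa = sst - ssw
    k = len(groups)
    with np.errstate(divide="ignore"):
        f = (ssa / (k - 1)) / (ssw / (n - k)) if ssw > 0 else np.inf
    return f, ssa / sst


def permanova(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``p = (1 + #{permuted F >= observed F}) / (1 + n_perm)`` with free
    permutation of sample labels.
    """
    if isinstance(groups, (dict, pd.Series)):
        labels = np.asarray([groups[s] for s in d.ids])
    else:
        labels = np.asarray(list(groups))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if counts.max() == d.n:
        raise ValidationError("a group equals the whole sample set")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    d2 = d.matrix**2
    f_obs, r2 = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_perm, _ = _pseudo_f(d2, perm)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, seed)


def core_microbiome(table: AbundanceTable, prevalence_threshold: float = 0.80) -> CoreSet:
    """ASVs present (count > 0) in at least ``ceil(threshold * n)`` samples,
    with the fraction of all reads those core members carry."""
    n = table.n_samples
    needed = math.ceil(prevalence_threshold * n)
    present = (table.counts > 0).sum(axis=1)
    members = present[present >= needed].index.tolist()
    total = table.counts.to_numpy().sum()
    fraction = float(table.counts.loc[members].to_numpy().sum() / total) if total else 0.0
    return CoreSet(members, prevalence_threshold, fraction)
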