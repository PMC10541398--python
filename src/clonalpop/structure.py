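"""Ordination and clustering: genotype PCA, IBS distances, classical MDS,
UPGMA dendrograms, and a small PCA utility for quantitative trait tables.

Genotype PCA uses allele-frequency normalization (each site centered by its
mean dosage and scaled by the binomial standard deviation sqrt(2*p*(1-p))),
the convention of SNP-PCA tooling; missing entries are mean-imputed before
centering.  Contribution ratios are eigenvalue shares of the full-rank
total, so they sum to 100% over all components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Sample coordinates plus per-component contribution ratios (%)."""

    coordinates: pd.DataFrame       # samples x retained components
    contributions: np.ndarray       # % of total variance, per retained component

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


def genotype_pca(
    matrix: GenotypeMatrix, n_components: int | None = None
) -> OrdinationResult:
    """PCA of the dosage matrix with allele-frequency scaling.

    Sites fixed (or entirely missing) after imputation carry no variance
    and are dropped.  Raises ``ValueError`` if nothing informative remains.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = matrix.calls.astype(float)
    X[matrix.calls == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    nan_cols = np.isnan(col_mean)
    p_hat = col_mean / 2.0
    with np.errstate(invalid="ignore"):
        scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    keep = ~nan_cols & (scale > 0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic sites; PCA undefined")
    X = X[:, keep]
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean[keep], inds[1])
    X = (X - col_mean[keep]) / scale[keep]

    U, s, _ = np.linalg.svd(X, full_matrices=False)
    lam = s**2
    total = lam.sum()
    if total == 0:
        raise ValueError("zero-variance matrix after scaling; PCA undefined")
    k = min(n_components or len(lam), len(lam))
    coords = pd.DataFrame(
        U[:, :k] * s[:k],
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return OrdinationResult(coords, 100.0 * lam[:k] / total)


def ibs_distance(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state distance matrix.

    Per pair, over sites non-missing in both: similarity is the mean
    fraction of shared alleles ``(2 - |g_i - g_j|) / 2``; distance is one
    minus that.  Pairs without shared sites get NaN and are logged.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    n = matrix.n_samples
    ids = matrix.sample_ids
    D = np.zeros((n, n))
    calls = matrix.calls
    valid = calls != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            if not shared.any():
                logger.warning("no shared sites for pair (%s, %s)", ids[i], ids[j])
                D[i, j] = D[j, i] = np.nan
                continue
            diff = np.abs(calls[i, shared].astype(int) - calls[j, shared].astype(int))
            D[i, j] = D[j, i] = 1.0 - np.mean((2.0 - diff) / 2.0)
    return pd.DataFrame(D, index=ids, columns=ids)


def classical_mds(D: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Torgerson classical (metric) multidimensional scaling.

    Double-centers the squared distances and embeds with the top-k
    eigenvectors scaled by sqrt(eigenvalue).  Negative eigenvalues
    (non-Euclidean distances) are dropped with a log note; ``k`` is
    reduced with a warning if fewer positive eigenvalues exist.
    """
    _check_distance_matrix(D)
    n = D.shape[0]
    D2 = np.asarray(D, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    lam, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    pos = lam > 1e-12 * max(lam.max(), 1.0)
    n_pos = int(pos.sum())
    n_neg = int((lam < -1e-12 * max(abs(lam).max(), 1.0)).sum())
    if n_neg:
        logger.info("classical_mds: dropped %d negative eigenvalues", n_neg)
    if k > n_pos:
        logger.warning("classical_mds: k reduced from %d to %d positive dims", k, n_pos)
        k = n_pos
    coords = pd.DataFrame(
        V[:, :k] * np.sqrt(lam[:k]),
        index=D.index,
        columns=[f"MDS{i + 1}" for i in range(k)],
    )
    total = lam[pos].sum()
    return OrdinationResult(coords, 100.0 * lam[:k] / total)


def _check_distance_matrix(D: pd.DataFrame) -> None:
    A = np.asarray(D, dtype=float)
    if np.isnan(A).any():
        bad = [
            (D.index[i], D.columns[j])
            for i, j in zip(*np.where(np.isnan(A)))
            if i < j
        ]
        raise ValueError(f"undefined distances for pairs: {bad}")
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(A), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")


@dataclass
class Dendrogram:
    """UPGMA tree: linkage matrix, leaf order, and Newick export."""

    sample_ids: list[str]           # lexicographically sorted leaf names
    linkage_matrix: np.ndarray      # scipy hierarchical-clustering encoding

    def newick(self) -> str:
        n = len(self.sample_ids)
        # node age = half the merge height, so cophenetic distance between
        # any two leaves equals the merge height (ultrametric convention)
        ages = {i: 0.0 for i in range(n)}
        labels = {i: f"{self.sample_ids[i]}" for i in range(n)}
        for r, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            age = h / 2.0
            la = f"{labels[a]}:{age - ages[a]:g}"
            lb = f"{labels[b]}:{age - ages[b]:g}"
            node = n + r
            labels[node] = f"({la},{lb})"
            ages[node] = age
        root = n + len(self.linkage_matrix) - 1
        return labels[root] + ";"

    def cophenetic(self) -> pd.DataFrame:
        C = squareform(cophenet(self.linkage_matrix))
        return pd.DataFrame(C, index=self.sample_ids, columns=self.sample_ids)


def upgma_tree(D: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram from a distance matrix.

    Samples are sorted lexicographically before agglomeration so that tied
    merges resolve identically regardless of input row order.
    """
    _check_distance_matrix(D)
    if D.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    ids = sorted(D.index)
    A = D.loc[ids, ids]
    Z = linkage(squareform(np.asarray(A, dtype=float), checks=False), method="average")
    return Dendrogram(ids, Z)


def trait_pca(table: pd.DataFrame, n_components: int | None = None) -> OrdinationResult:
    """PCA of a samples x numeric-traits table with z-score standardization.

    Zero-variance traits are dropped with a warning; missing values are a
    hard error (trait tables are small enough to curate).
    """
    if table.isna().any().any():
        raise ValueError("trait table contains missing values")
    if len(table) < 2:
        raise ValueError("need >= 2 samples")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [c for c, k in zip(table.columns, keep) if not k]
    if dropped:
        logger.warning("trait_pca: dropped zero-variance traits %s", dropped)
    if keep.sum() == 0:
        raise ValueError("no traits with variance")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    lam = s**2
    k = min(n_components or len(lam), len(lam))
    coords = pd.DataFrame(
        U[:, :k] * s[:k],
        index=table.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return OrdinationResult(coords, 100.0 * lam[:k] / lam.sum())
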