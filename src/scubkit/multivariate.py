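"""Clustering and ordination of per-genome SCUB profiles.

Genomes are compared through a feature matrix whose rows are genomes and
whose columns are stratified SCUB statistics (e.g. the per-codon frequencies
in each intron-number bin).  Two views are provided: agglomerative
hierarchical clustering (Euclidean distance, complete linkage by default)
exported as a Newick tree, and PCA with a varimax rotation of the first two
components, reported as rotated scores for scatter plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio import TreeNode
from sklearn.decomposition import PCA
from statsmodels.multivariate.factor_rotation import rotate_factors

from .scub_stats import ScubProfile

logger = logging.getLogger(__name__)


def build_profile_matrix(
    profiles_by_genome: dict[str, dict[object, ScubProfile]],
    which: tuple[str, ...] = ("third_class", "at_gc_ratio", "per_codon"),
    stratum_filter=None,
) -> pd.DataFrame:
    """Assemble the genome x feature matrix from per-stratum profiles.

    Parameters
    ----------
    profiles_by_genome
        genome label -> {stratum key -> profile}.  Stratum keys may be
        intron bins (ints) or (exon_total, exon_index) tuples.
    which
        Statistic blocks to concatenate per stratum.
    stratum_filter
        Optional predicate on the stratum key (e.g. keep first exons only:
        ``lambda k: k[1] == 0``).

    Missing cells (strata empty in one genome but not all) are imputed by the
    column mean; the imputation count is logged.  Columns missing everywhere
    are dropped.
    """
    if len(profiles_by_genome) < 2:
        raise ValueError("need >= 2 genomes")
    rows = {}
    for genome, strata in profiles_by_genome.items():
        parts = []
        for key in sorted(strata, key=str):
            if stratum_filter is not None and not stratum_filter(key):
                continue
            parts.append(strata[key].to_feature_series(which=which).add_prefix(f"{key}|"))
        if not parts:
            raise ValueError(f"genome {genome!r}: no strata after filtering")
        rows[genome] = pd.concat(parts)
    matrix = pd.DataFrame(rows).T
    matrix = matrix.dropna(axis=1, how="all")
    n_missing = int(matrix.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d missing cells by column mean", n_missing)
        matrix = matrix.fillna(matrix.mean(axis=0))
    if matrix.isna().any().any():
        raise ValueError("matrix still has missing values after imputation")
    return matrix


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree).strip()

    def leaves_in_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster membership at k clusters."""
        flat = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of the profile matrix rows.

    Euclidean distance with complete linkage by default; both switchable.
    Rows are sorted by label before linkage so the tree is invariant to input
    row order (leaf order deterministic).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"duplicate row labels: {dupes}")
    ordered = matrix.sort_index()
    dists = pdist(ordered.to_numpy(dtype=float), metric=metric)
    z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(linkage_matrix=z, labels=list(ordered.index))


@dataclass
class PcaResult:
    scores: pd.DataFrame  # genomes x (PC1, PC2), varimax-rotated
    loadings: pd.DataFrame  # features x (PC1, PC2), varimax-rotated
    explained_variance_ratio: np.ndarray  # of the unrotated components
    n_dropped_columns: int


def pca_varimax(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of genome profiles with varimax rotation of the first two PCs.

    Columns are standardized to zero mean / unit variance by default
    (features mix frequencies and ratios of different scales); zero-variance
    columns are dropped and counted.  The first two principal axes are
    rotated by varimax (an orthogonal rotation, so the total variance of the
    component pair is conserved) and a deterministic sign convention is
    applied: in each rotated component the largest-magnitude loading is
    positive.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 rows for a meaningful rotation")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate row labels")
    x = matrix.to_numpy(dtype=float)
    std = x.std(axis=0, ddof=0)
    keep = std > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance columns", n_dropped)
    x = x[:, keep]
    columns = matrix.columns[keep]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 usable (non-constant) columns")
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    else:
        x = x - x.mean(axis=0)

    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(x)
    axes = pca.components_.T  # features x 2, orthonormal columns
    rotated, _ = rotate_factors(axes, "varimax")
    # Deterministic sign: largest |loading| positive in each component.
    for j in range(rotated.shape[1]):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] = -rotated[:, j]
    scores = x @ rotated
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=["PC1", "PC2"]),
        loadings=pd.DataFrame(rotated, index=columns, columns=["PC1", "PC2"]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_dropped_columns=n_dropped,
    )
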