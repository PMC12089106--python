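"""Structure analysis: PCA over genes and hierarchical clustering.

PCA treats genes as observations and samples as variables, so component
scores live on genes and loadings on samples.  Clustering runs in both
orientations: samples on their full gene profiles (dendrogram, Newick
export) and genes into ``k`` subgroup profiles via a tree cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ArgumentError
from .expression import ExpressionMatrix

METRICS = ("euclidean", "cityblock", "correlation", "cosine")
LINKAGES = ("ward", "average", "complete", "single")


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the sample-by-sample covariance/correlation.

    ``scores``: (n_genes, n_components); ``loadings``: (n_samples,
    n_components), orthonormal columns with a deterministic sign convention
    (the largest-magnitude loading of each component is positive);
    ``variance_proportion`` sums to 1 with components in decreasing order.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_proportion: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.gene_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.loadings, index=self.sample_ids, columns=cols)


def pca(matrix: ExpressionMatrix, standardize: bool = True) -> PCAResult:
    """PCA with genes as observations and samples as variables.

    With ``standardize`` the sample columns are scaled to unit variance
    (correlation PCA); a constant column is then an error naming the
    sample.  Scores are coordinates of genes on the components; loadings
    are the per-sample weights.
    """
    if matrix.n_samples < 2 or matrix.n_genes < 2:
        raise ArgumentError("PCA needs >= 2 genes and >= 2 samples")
    x = matrix.values.astype(float)
    x = x - x.mean(axis=0, keepdims=True)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        const = np.flatnonzero(sd == 0)
        if const.size:
            raise ArgumentError(
                f"constant sample column under standardization: "
                f"{matrix.sample_ids[const[0]]!r}"
            )
        x = x / sd
    cov = (x.T @ x) / (matrix.n_genes - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading per component is positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    total = eigval.sum()
    prop = eigval / total if total > 0 else np.full_like(eigval, 1.0 / eigval.size)
    scores = x @ eigvec
    return PCAResult(
        scores=scores,
        loadings=eigvec,
        variance_proportion=prop,
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class DendrogramNode:
    """Binary merge tree; leaves carry a sample identifier."""

    merge_height: float
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None
    leaf: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf]
        return self.children[0].leaves() + self.children[1].leaves()

    def to_newick(self) -> str:
        def render(node: "DendrogramNode", parent_height: float) -> str:
            length = parent_height - node.merge_height
            if node.is_leaf:
                return f"{node.leaf}:{length:.6g}"
            left = render(node.children[0], node.merge_height)
            right = render(node.children[1], node.merge_height)
            return f"({left},{right}):{length:.6g}"

        if self.is_leaf:
            return f"{self.leaf};"
        left = render(self.children[0], self.merge_height)
        right = render(self.children[1], self.merge_height)
        return f"({left},{right});"


def _tree_from_linkage(z: np.ndarray, labels: list[str]) -> DendrogramNode:
    n = len(labels)
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(merge_height=0.0, leaf=labels[i]) for i in range(n)
    }
    for i, (a, b, height, _) in enumerate(z):
        nodes[n + i] = DendrogramNode(
            merge_height=float(height), children=(nodes[int(a)], nodes[int(b)])
        )
    return nodes[n + len(z) - 1]


def _linkage_matrix(
    obs: np.ndarray, metric: str, linkage: str
) -> np.ndarray:
    if metric not in METRICS:
        raise ArgumentError(f"unknown metric {metric!r}; one of {METRICS}")
    if linkage not in LINKAGES:
        raise ArgumentError(f"unknown linkage {linkage!r}; one of {LINKAGES}")
    if linkage == "ward" and metric != "euclidean":
        raise ArgumentError("ward linkage requires the euclidean metric")
    dist = pdist(obs, metric=metric)
    return hierarchy.linkage(dist, method=linkage)


def hierarchical_cluster(
    matrix: ExpressionMatrix, metric: str = "euclidean", linkage: str = "ward"
) -> DendrogramNode:
    """Cluster samples on their gene-expression profiles.

    Ties are broken deterministically by input sample order (SciPy's
    linkage is deterministic for fixed input ordering).
    """
    if matrix.n_samples < 2:
        raise ArgumentError("clustering needs >= 2 samples")
    z = _linkage_matrix(matrix.values.T, metric, linkage)
    return _tree_from_linkage(z, list(matrix.sample_ids))


def gene_clusters(
    matrix: ExpressionMatrix,
    k: int,
    seed: int = 0,
    metric: str = "euclidean",
    linkage: str = "average",
) -> pd.DataFrame:
    """Partition genes into ``k`` clusters by cutting a gene-wise tree.

    Returns one row per gene with a 1-based ``cluster`` index plus the
    cluster's mean profile per sample.  ``seed`` is accepted for interface
    stability; the tree cut itself is deterministic.
    """
    del seed  # deterministic tree cut; kept for a stable interface
    if not 1 <= k <= matrix.n_genes:
        raise ArgumentError(f"k must be in [1, {matrix.n_genes}], got {k}")
    if k == matrix.n_genes:
        assign = np.arange(matrix.n_genes)
    elif k == 1:
        assign = np.zeros(matrix.n_genes, dtype=int)
    else:
        z = _linkage_matrix(matrix.values, metric, linkage)
        assign = hierarchy.cut_tree(z, n_clusters=k).ravel()
    # relabel clusters 1..k in order of first appearance for determinism
    relabel: dict[int, int] = {}
    labels = np.empty(matrix.n_genes, dtype=int)
    for i, a in enumerate(assign):
        if a not in relabel:
            relabel[a] = len(relabel) + 1
        labels[i] = relabel[a]
    rows = []
    for gi, gene in enumerate(matrix.gene_ids):
        c = int(labels[gi])
        members = labels == c
        profile = matrix.values[members, :].mean(axis=0)
        row = {"gene_id": gene, "cluster": c}
        row.update(
            {f"profile_{s}": float(v) for s, v in zip(matrix.sample_ids, profile)}
        )
        rows.append(row)
    return pd.DataFrame(rows)
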