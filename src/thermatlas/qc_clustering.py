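"""Sample-level quality control: PCA of log-CPM and Pearson clustering.

Both operations work on log2(CPM + 1) profiles — the pseudo-count keeps
zero counts finite and is recorded in the run manifest.  PCA is deterministic
up to component sign, which is fixed by making each component's
largest-magnitude gene loading positive.  Hierarchical clustering uses
distance 1 - Pearson with average linkage by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from scipy.spatial.distance import squareform

from .io_formats import CountMatrix
from .normalization_de import _as_frame, compute_cpm

__all__ = [
    "PcaResult",
    "pca_samples",
    "CorrelationClustering",
    "pearson_cluster",
    "to_newick",
    "all_tissue_genes",
]


def log_cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return np.log2(compute_cpm(counts) + 1.0)


def all_tissue_genes(expressed_flags: pd.DataFrame) -> pd.Index:
    """Genes detected in every tissue (combined-PCA universe)."""
    return expressed_flags.index[expressed_flags.all(axis=1)]


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x PC1..PCk
    variance_explained: np.ndarray  # fractions, non-increasing
    genes: list[str]


def pca_samples(
    counts: CountMatrix | pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    k: int = 2,
) -> PcaResult:
    """PCA of samples over centered log2(CPM + 1) profiles.

    ``gene_subset`` restricts the gene universe (default: all genes);
    ``k`` components are returned and must not exceed min(samples - 1,
    genes).
    """
    df = _as_frame(counts)
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in df.index]
        if missing:
            raise ValueError(f"gene_subset ids absent from counts: {missing[:5]}")
        df = df.loc[list(gene_subset)]
    x = log_cpm(df).to_numpy().T  # samples x genes
    max_k = min(x.shape[0] - 1, x.shape[1])
    if k > max_k:
        raise ValueError(f"k={k} exceeds min(samples - 1, genes) = {max_k}")
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix signs: largest-magnitude loading of each component positive
    for j in range(len(s)):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    coords = pd.DataFrame(
        (u[:, :k] * s[:k]),
        index=df.columns,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return PcaResult(coords, frac[:k], list(df.index))


@dataclass
class CorrelationClustering:
    correlation: pd.DataFrame  # sample x sample Pearson, unit diagonal
    merge_tree: np.ndarray  # scipy linkage matrix
    method: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.correlation.index)

    def cut(self, n_clusters: int) -> pd.Series:
        labels = cut_tree(self.merge_tree, n_clusters=n_clusters).ravel()
        return pd.Series(labels, index=self.sample_ids, name="cluster")


def pearson_cluster(
    counts: CountMatrix | pd.DataFrame, method: str = "average"
) -> CorrelationClustering:
    """Agglomerative clustering of samples at distance 1 - Pearson(log-CPM).

    A constant expression profile has undefined correlation and is an error
    naming the sample.
    """
    x = log_cpm(counts)
    if x.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    sd = x.std(axis=0)
    flat = sd[sd < 1e-10]
    if len(flat):
        raise ValueError(
            f"constant expression profile for sample {flat.index[0]!r}; "
            "correlation undefined"
        )
    corr = x.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    return CorrelationClustering(corr, z, method)


def to_newick(clustering: CorrelationClustering) -> str:
    """Serialize the merge tree as a Newick string with branch lengths."""
    tree = to_tree(clustering.merge_tree)
    labels = clustering.sample_ids

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
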