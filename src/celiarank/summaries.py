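"""Sample-level PCA and gene-level hierarchical clustering views.

Both operate on a variance-stabilizing transform of the normalized
counts: ``log2(normalized count + pseudocount)``.  PCA runs on the
top-variance genes after gene-centering; the clustering result carries
the numeric leaf orders and the row-scaled display matrix — rendering is
left to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import CountMatrix, ValidationError

__all__ = [
    "transform_for_clustering",
    "pca_samples",
    "hierarchical_cluster",
    "PcaResult",
    "ClusteringResult",
]


def transform_for_clustering(
    counts: CountMatrix, norm_factors: pd.Series | None = None, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(depth-normalized count + pseudocount).

    Counts are rescaled to a fixed per-million depth (CPM), so scaling
    every sample's depth equally leaves the output unchanged.
    """
    lib = counts.library_sizes.to_numpy(float)
    f = (
        np.ones_like(lib)
        if norm_factors is None
        else norm_factors.reindex(counts.sample_ids).to_numpy(float)
    )
    if (f <= 0).any():
        raise ValidationError("normalization factors must be positive")
    eff = lib * f
    normalized = counts.counts.to_numpy(float) / eff[None, :] * 1e6
    return pd.DataFrame(
        np.log2(normalized + pseudocount), index=counts.gene_ids, columns=counts.sample_ids
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray  # fraction per component


def pca_samples(matrix: pd.DataFrame, n_top_genes: int = 500, n_components: int = 10) -> PcaResult:
    """PCA of samples on the top-variance genes.

    Genes are centered; components come from the singular decomposition
    with a deterministic sign convention (the largest-|loading| entry of
    each component is positive).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    variances = matrix.var(axis=1, ddof=1)
    if float(variances.max()) == 0.0:
        raise ValidationError("matrix is constant; no variance to decompose")
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    x = matrix.loc[top].to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| entry positive
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    total_var = (x**2).sum()
    var_frac = (s**2) / total_var if total_var > 0 else np.zeros(k)
    comp = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(vt.T, index=top, columns=comp),
        variance_explained=var_frac,
    )


@dataclass
class ClusteringResult:
    gene_order: list
    sample_order: list
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    scaled_matrix: pd.DataFrame


def hierarchical_cluster(matrix: pd.DataFrame, row_scale: bool = True) -> ClusteringResult:
    """Complete-linkage hierarchical clustering of genes (rows) and samples
    (columns) on Euclidean distances.

    With ``row_scale`` each gene is z-scaled for display; zero-variance
    rows are dropped with a warning since they cannot be scaled.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 rows")
    data = matrix.copy()
    if row_scale:
        sd = data.std(axis=1, ddof=0)
        dead = sd[sd == 0].index
        if len(dead) > 0:
            warnings.warn(
                f"dropping {len(dead)} zero-variance row(s) before scaling",
                stacklevel=2,
            )
            data = data.drop(index=dead)
            if data.shape[0] < 2:
                raise ValidationError("fewer than 2 rows left after dropping")
            sd = sd.drop(index=dead)
        data = data.sub(data.mean(axis=1), axis=0).div(sd, axis=0)
    gene_link = hierarchy.linkage(pdist(data.to_numpy()), method="complete")
    sample_link = hierarchy.linkage(pdist(data.to_numpy().T), method="complete")
    gene_order = [data.index[i] for i in hierarchy.leaves_list(gene_link)]
    sample_order = [data.columns[i] for i in hierarchy.leaves_list(sample_link)]
    return ClusteringResult(
        gene_order=gene_order,
        sample_order=sample_order,
        gene_linkage=gene_link,
        sample_linkage=sample_link,
        scaled_matrix=data,
    )
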