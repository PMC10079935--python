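"""Global structure: hierarchical clustering, PCA, and gene loadings.

Clustering follows the classical expression-analysis recipe: agglomerative
average linkage on pairwise Euclidean distances, applied to genes or to
arrays (for the heatmap view, on the gene-centered log matrix).  PCA is
correlation-based: every gene row is standardized (mean 0, sd 1 across
samples) before the singular value decomposition of the samples-by-genes
data, which is equivalent to an eigendecomposition of the sample
correlation structure.  "Factor loading" of a gene on a component is the
Pearson correlation between the gene's expression profile across arrays
and the component's score vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import DataError, ExpressionMatrix

logger = logging.getLogger("ltsp_sig")


@dataclass
class Dendrogram:
    """Average-linkage merge tree.

    ``merges`` rows are ``(node_a, node_b, height)`` where nodes 0..n-1 are
    the leaves (in ``leaves`` order) and node n+i is the cluster created by
    merge i; heights are average-linkage Euclidean distances and must be
    non-decreasing along the agglomeration sequence.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise DataError("non-monotone merge heights in average-linkage tree")

    @property
    def linkage_matrix(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage matrix (cluster sizes recomputed)."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        out = np.zeros((len(self.merges), 4))
        for i, (a, b, h) in enumerate(self.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            out[i] = (a, b, h, sizes[n + i])
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        node = {i: _quote(self.leaves[i]) for i in range(n)}
        for i, (a, b, h) in enumerate(self.merges):
            la, lb = h - height[a], h - height[b]
            node[n + i] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + i] = h
        return node[n + len(self.merges) - 1] + ";"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "samples") -> Dendrogram:
    """Average-linkage clustering of genes or samples on Euclidean distance.

    Deterministic given input order (SciPy's nearest-neighbor chain breaks
    ties by smaller index pair).
    """
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    if axis == "genes":
        data = matrix.values.to_numpy()
        labels = matrix.gene_ids
    else:
        data = matrix.values.to_numpy().T
        labels = matrix.sample_ids
    if data.shape[0] < 2:
        raise DataError(f"need >= 2 items on axis {axis!r} to cluster")
    Z = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(leaves=list(labels), merges=merges)


@dataclass
class PcaResult:
    """PCA of the normalized matrix.

    scores : samples x components (projections of arrays).
    variance_fraction : per-component fraction of total variance, sums to 1.
    loadings : genes x components Pearson correlations between each gene's
        profile and each component's score vector (NaN for genes whose
        variance is zero).
    """

    scores: pd.DataFrame
    variance_fraction: np.ndarray
    loadings: pd.DataFrame

    def __post_init__(self) -> None:
        total = float(np.sum(self.variance_fraction))
        if abs(total - 1.0) > 1e-8:
            raise DataError(f"variance fractions sum to {total}, expected 1")
        lo = self.loadings.to_numpy()
        if np.nanmax(np.abs(lo), initial=0.0) > 1.0 + 1e-9:
            raise DataError("loadings outside [-1, 1]")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: ExpressionMatrix, standardize_genes: bool = True) -> PcaResult:
    """Correlation-based PCA of arrays.

    Gene rows are standardized (mean 0, sd 1 across samples) by default —
    the correlation-matrix reading; ``standardize_genes=False`` centers only
    (covariance-based PCA).  Zero-variance genes are dropped with a warning.
    Component signs are fixed so the lexicographically first sample's score
    is >= 0 on every component.  Requires >= 3 samples.
    """
    if matrix.n_samples < 3:
        raise DataError("PCA needs >= 3 samples")
    vals = matrix.values.to_numpy(dtype=float)
    sds = vals.std(axis=1, ddof=1)
    keep = sds > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("pca: dropped %d zero-variance gene(s)", dropped)
    vals = vals[keep]
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]

    centered = vals - vals.mean(axis=1, keepdims=True)
    X = centered / sds[keep][:, None] if standardize_genes else centered

    # samples as observations in gene space; row means of X are 0 already
    Y = X.T  # samples x genes
    U, S, _ = np.linalg.svd(Y - Y.mean(axis=0, keepdims=True), full_matrices=False)
    n_comp = min(matrix.n_samples - 1, len(genes))
    U, S = U[:, :n_comp], S[:n_comp]
    scores = U * S

    # deterministic sign: lexicographically first sample scores >= 0
    first = int(np.argmin(np.asarray(matrix.sample_ids, dtype=object)))
    flip = np.where(scores[first] < 0, -1.0, 1.0)
    scores = scores * flip

    var = S ** 2
    var_frac = var / var.sum()

    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    scores_df = pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names)

    loadings = np.empty((len(genes), n_comp))
    for k in range(n_comp):
        loadings[:, k] = _pearson_rows(vals, scores[:, k])
    loadings_df = pd.DataFrame(loadings, index=genes, columns=comp_names)
    return PcaResult(scores=scores_df, variance_fraction=var_frac, loadings=loadings_df)


def _pearson_rows(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson correlation of each matrix row with a vector."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = rc @ vc / denom
    out[denom == 0] = np.nan
    return out


def gene_loadings(matrix: ExpressionMatrix, scores: np.ndarray | pd.Series) -> pd.Series:
    """Per-gene Pearson correlation with a component score vector.

    Genes with zero variance across samples get NaN (loading undefined).
    """
    vec = np.asarray(scores, dtype=float)
    if vec.shape != (matrix.n_samples,):
        raise DataError(f"score vector length {vec.shape} does not match "
                        f"{matrix.n_samples} samples")
    vals = matrix.values.to_numpy(dtype=float)
    return pd.Series(_pearson_rows(vals, vec), index=matrix.gene_ids)
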