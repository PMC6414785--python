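"""Descriptive sample structure: PCA and hierarchical sample clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .merge import MergedStudy

__all__ = ["PCAResult", "SampleTree", "pca", "cluster_samples"]


@dataclass
class PCAResult:
    """Covariance (or correlation) PCA of samples over gene variables.

    ``variance_fraction`` covers *all* computable components and sums to 1;
    ``scores``/``loadings`` hold the requested leading components. The sign
    of each component is fixed so its largest-magnitude loading is positive.
    """

    scores: pd.DataFrame        # sample × component
    loadings: pd.DataFrame      # gene × component
    variance_fraction: np.ndarray
    centered: bool = True
    scaled: bool = False


def pca(ms: MergedStudy, n_components: int | None = None,
        scale_genes: bool = False) -> PCAResult:
    """PCA with samples as observations and genes as variables.

    Gene rows are centered (and unit-scaled when ``scale_genes``);
    components are ordered by explained variance.
    """
    x = ms.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    max_comp = min(n_genes, n_samples - 1)
    if n_components is None:
        n_components = min(3, max_comp)
    if n_components > max_comp:
        raise ValueError(f"n_components > {max_comp}")
    xc = x - x.mean(axis=1, keepdims=True)
    if scale_genes:
        sd = x.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance gene under scale_genes=True")
        xc = xc / sd[:, None]
    if not np.any(xc):
        raise ValueError("constant matrix: PCA undefined")
    u, s, vt = np.linalg.svd(xc.T, full_matrices=False)   # samples × genes
    s = s[:max_comp]
    var = s ** 2
    frac = var / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(n_components):
        i = int(np.abs(loadings[:, j]).argmax())
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=ms.samples, columns=cols),
        loadings=pd.DataFrame(loadings, index=ms.genes, columns=cols),
        variance_fraction=frac,
        scaled=scale_genes,
    )


@dataclass
class SampleTree:
    """Hierarchical sample clustering result (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]
    metric: str = "euclidean"
    method: str = "average"

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        n = len(self.labels)

        def height(i: int) -> float:
            return 0.0 if i < n else float(self.linkage[i - n, 2])

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.linkage[i - n]
            parts = [f"{node(int(c))}:{h - height(int(c)):.9g}" for c in (a, b)]
            return f"({','.join(parts)})"

        return node(2 * n - 2) + ";"


def cluster_samples(ms: MergedStudy, gene_subset: list[str] | None = None,
                    linkage: str = "average") -> SampleTree:
    """Euclidean-distance hierarchical clustering of sample profiles,
    optionally restricted to a gene subset."""
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = ms.values
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in values.index]
        if missing:
            raise ValueError(f"unknown genes in subset: {missing[:10]}")
        values = values.loc[list(gene_subset)]
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    d = pdist(values.to_numpy(dtype=float).T, metric="euclidean")
    z = hierarchy.linkage(d, method=linkage)
    return SampleTree(linkage=z, labels=list(values.columns), method=linkage)
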