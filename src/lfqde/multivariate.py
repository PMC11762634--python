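"""PCA with scree proportions and hierarchical clustering (UPGMA).

PCA is computed by singular value decomposition of the centred (and by
default unit-variance scaled) samples x proteins matrix, so the explained
variance proportions are sigma_i^2 / sum(sigma^2). Clustering follows the
heatmap workflow: a pairwise distance matrix — 1 - Pearson r by default,
Euclidean as an alternative — fed to unweighted average linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Sample scores, protein loadings and per-component variance shares."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins (kept) x components
    variance_explained: np.ndarray  # proportions, sum to 1


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` row i joins cluster ids a, b (leaves are 0..n-1, the cluster
    formed at row i gets id n+i) at ``heights[i]``; ``leaf_order`` is the
    display order of the leaves; ``labels`` names them.
    """

    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,)
    leaf_order: np.ndarray  # (n,) int
    labels: list

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"left": self.merges[:, 0], "right": self.merges[:, 1], "height": self.heights}
        )


def pca(data: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA of samples over proteins via SVD.

    ``data`` is proteins x samples and must be complete (use one imputation
    cycle or the across-cycle mean). Scaling divides each protein by its
    across-sample sd (n-1); zero-variance proteins are dropped with a warning
    when scaling.
    """
    if data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if data.isna().to_numpy().any():
        raise ValueError("matrix must be complete (impute first)")
    X = data.T.to_numpy(dtype=float)  # samples x proteins
    kept = data.index
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance proteins before scaling", int((~keep).sum()))
            X = X[:, keep]
            kept = data.index[keep]
            sd = sd[keep]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S**2).sum())
    if total == 0:
        raise ValueError("matrix has no variance")
    var_explained = S**2 / total
    comps = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=data.columns, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=kept, columns=comps)
    return PCAResult(scores=scores, loadings=loadings, variance_explained=var_explained)


def correlation_distance(
    data: pd.DataFrame,
    axis: str = "columns",
    absolute: bool = False,
) -> pd.DataFrame:
    """Pearson-correlation dissimilarity, d = 1 - r (or 1 - |r|).

    ``axis='columns'`` compares samples; ``axis='rows'`` compares proteins.
    Items with zero variance have undefined correlation and are rejected.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    items = data.T if axis == "columns" else data
    if items.shape[0] < 2:
        raise ValueError("need >= 2 items")
    arr = items.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = items.index[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance item: {bad!r}")
    r = np.corrcoef(arr)
    d = 1.0 - np.abs(r) if absolute else 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=items.index, columns=items.index)


def euclidean_distance(data: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Pairwise Euclidean distances between samples or proteins."""
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    items = data.T if axis == "columns" else data
    d = squareform(pdist(items.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=items.index, columns=items.index)


def distance_matrix(data: pd.DataFrame, metric: str = "pearson", axis: str = "columns") -> pd.DataFrame:
    """Dispatch between the correlation (default) and Euclidean metrics."""
    if metric == "pearson":
        return correlation_distance(data, axis=axis)
    if metric == "euclidean":
        return euclidean_distance(data, axis=axis)
    raise ValueError(f"unknown metric {metric!r}")


def average_linkage(distances: Union[pd.DataFrame, np.ndarray]) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) clustering of a distance matrix."""
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(
        merges=Z[:, :2].astype(int),
        heights=Z[:, 2].copy(),
        leaf_order=hierarchy.leaves_list(Z),
        labels=labels,
    )
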