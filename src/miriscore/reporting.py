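"""Unsupervised views (PCA, hierarchical clustering), row scaling, H-score bins."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigError

__all__ = [
    "row_scale_minmax",
    "hierarchical_cluster",
    "pca_project",
    "hscore_classify",
    "ClusterResult",
]


def row_scale_minmax(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row linearly to [-1, 1]; constant rows become all zeros."""
    x = matrix.to_numpy(dtype=float)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = 2.0 * (x - lo) / span - 1.0
    scaled[np.repeat(span == 0, x.shape[1], axis=1)] = 0.0
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage matrix over samples
    leaf_order: list[str]
    labels: pd.Series            # cluster label per sample at the requested cut


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
    k: int = 2,
    scale_rows: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of samples (columns) on the row-scaled matrix."""
    if matrix.shape[1] < 2:
        raise ConfigError("clustering needs at least two samples")
    if matrix.isna().to_numpy().any():
        raise ConfigError("matrix contains NaN")
    data = row_scale_minmax(matrix) if scale_rows else matrix
    dist = pdist(data.to_numpy(dtype=float).T, metric=metric)
    z = linkage(dist, method=method)
    order = [matrix.columns[i] for i in leaves_list(z)]
    labels = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=matrix.columns)
    return ClusterResult(linkage=z, leaf_order=order, labels=labels)


def pca_project(
    matrix: pd.DataFrame, center: bool = True, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from a features x samples matrix via SVD.

    Returns (coordinates: samples x PCs, variance-explained fractions). The
    sign of each component is fixed so its largest-magnitude feature loading is
    positive.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ConfigError("PCA needs >= 2 features and >= 2 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    u = u * signs
    coords = u * s
    total = (s ** 2).sum()
    var_frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.columns, columns=cols), var_frac


def hscore_classify(h: float) -> str:
    """Bin an H-score: absent (0), low (1-100), intermediate (101-200),
    strong (201-300)."""
    if not (0 <= h <= 300):
        raise ValueError(f"H-score {h} outside [0, 300]")
    if h == 0:
        return "absent"
    if h <= 100:
        return "low"
    if h <= 200:
        return "intermediate"
    return "strong"
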