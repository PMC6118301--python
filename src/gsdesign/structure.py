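"""Population-structure analysis: dissimilarity, K-means and PCA.

The panel's structure is quantified from the marker data alone: a simple
mismatch dissimilarity between lines, K-means clustering of each line's
dissimilarity profile (with an elbow scan over the cluster count), and
principal-component scores of the column-centred marker matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .genotypes import GenotypeMatrix

__all__ = [
    "DissimilarityMatrix",
    "ClusterAssignment",
    "PcaScores",
    "genetic_dissimilarity",
    "scan_k",
    "kmeans_partition",
    "pca_scores",
]


@dataclass
class DissimilarityMatrix:
    line_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity shape mismatch")
        if (self.values < 0).any():
            raise ValueError("negative dissimilarity")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("dissimilarity diagonal not zero")


@dataclass
class ClusterAssignment:
    line_ids: np.ndarray
    labels: np.ndarray          # integer cluster labels in 1..k
    k: int
    within_ss: float
    seed: int

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("cluster labels outside 1..k")
        if len(np.unique(self.labels)) != self.k:
            raise ValueError("empty cluster in assignment")

    def members(self, label: int) -> np.ndarray:
        return self.line_ids[self.labels == label]

    def series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.line_ids))


@dataclass
class PcaScores:
    line_ids: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray   # fractions, non-increasing


def genetic_dissimilarity(G: GenotypeMatrix) -> DissimilarityMatrix:
    """Simple-mismatch dissimilarity: fraction of markers with differing codes."""
    if G.n_lines < 2:
        raise ValueError("dissimilarity needs at least two lines")
    D = squareform(pdist(G.calls, metric="hamming"))
    return DissimilarityMatrix(G.line_ids, D)


def scan_k(D: DissimilarityMatrix, k_min: int = 2, k_max: int = 50,
           restarts: int = 25, seed: int = 0) -> pd.DataFrame:
    """Elbow scan: best within-cluster SS per cluster count.

    K-means runs on the rows of ``D`` (each line's dissimilarity profile),
    ``restarts`` initialisations per k, keeping the lowest within-SS.
    """
    if k_max >= len(D.line_ids):
        raise ValueError("k_max must be below the line count")
    records = []
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed + k)
        km.fit(D.values)
        records.append({"k": k, "within_ss": float(km.inertia_)})
    return pd.DataFrame(records)


def kmeans_partition(D: DissimilarityMatrix, k: int = 5, restarts: int = 25,
                     seed: int = 0) -> ClusterAssignment:
    """Best-of-restarts K-means partition of the dissimilarity profiles."""
    if k < 1:
        raise ValueError("k must be positive")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(D.values) + 1
    return ClusterAssignment(D.line_ids, labels, k, float(km.inertia_), seed)


def pca_scores(G: GenotypeMatrix, n_components: int = 3) -> PcaScores:
    """PCA of the column-centred marker matrix (no variance scaling)."""
    n_components = min(n_components, G.n_lines, G.n_markers)
    X = G.calls - G.calls.mean(axis=0, keepdims=True)
    p = PCA(n_components=n_components, svd_solver="randomized",
            random_state=0)
    scores = p.fit_transform(X)
    return PcaScores(G.line_ids, scores, p.explained_variance_ratio_)
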