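"""Exploratory dimensionality reduction and clustering.

PCA is run on the raw 0/1 matrix with mean-centered columns (no unit
scaling) to summarize how many components recover a target fraction of
the total variance (default 90%) and to give a 2-D projection of the
genomes.  Clustering of the projection is centroid-based (k-means) with
the cluster count chosen at the elbow of the within-cluster dispersion
curve.  These outputs are for visualization only and never feed the
feature-selection stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .pangenome import PangenomeMatrix

__all__ = ["PcaResult", "run_pca", "elbow_select_k", "cluster"]


@dataclass
class PcaResult:
    explained_variance_ratio: np.ndarray
    cumulative_curve: np.ndarray
    n_components_90: int
    projection_2d: np.ndarray  # genomes x 2


def run_pca(pangenome: PangenomeMatrix, target_variance: float = 0.90) -> PcaResult:
    """PCA of the presence/absence matrix.

    Components are ordered by decreasing explained variance;
    ``n_components_90`` is the smallest component count whose cumulative
    explained-variance ratio reaches ``target_variance``.  The 2-D
    projection uses the top two components (or one, padded with zeros,
    if only one direction of variance exists).
    """
    X = pangenome.matrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genomes and 2 families")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("no variance: matrix is constant across genomes")

    n_components = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratio)
    n90 = int(np.searchsorted(cumulative, target_variance) + 1)
    n90 = max(1, min(n90, len(ratio)))

    projection = scores[:, :2]
    if projection.shape[1] < 2:
        projection = np.column_stack([projection, np.zeros(len(projection))])
    return PcaResult(
        explained_variance_ratio=ratio,
        cumulative_curve=cumulative,
        n_components_90=n90,
        projection_2d=projection,
    )


def _dispersion_curve(embedding: np.ndarray, ks: range, seed: int) -> np.ndarray:
    inertia = np.empty(len(ks))
    for idx, k in enumerate(ks):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(embedding)
        inertia[idx] = km.inertia_
    return inertia


def elbow_select_k(
    embedding: np.ndarray, k_min: int = 1, k_max: int | None = None, seed: int = 0
) -> int:
    """Pick a cluster count at the elbow of the dispersion-vs-k curve.

    Fits k-means for each k in [k_min, k_max], records the within-cluster
    sum of squares, and returns the k with the largest curvature
    (second difference of the dispersion curve).  Flat curves (e.g. all
    points identical) fall back to ``k_min``.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = len(embedding)
    if k_max is None:
        k_max = min(10, n)
    if k_max < k_min:
        raise ValueError(f"k_max ({k_max}) < k_min ({k_min})")
    if k_max > n:
        raise ValueError(f"k_max ({k_max}) exceeds number of points ({n})")
    if k_min == k_max:
        return k_min

    ks = range(k_min, k_max + 1)
    inertia = _dispersion_curve(embedding, ks, seed)
    if len(inertia) < 3 or np.allclose(inertia, inertia[0]):
        return k_min
    # Curvature at interior points; the elbow is the largest positive bend.
    second_diff = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
    best = int(np.argmax(second_diff))
    return list(ks)[best + 1]


def cluster(embedding: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Centroid-based partition of the embedding into k clusters.

    Labels are arbitrary integers but stable for a fixed seed.  ``k = 1``
    (a supported degenerate case) puts every genome in one cluster.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = len(embedding)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(embedding)
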