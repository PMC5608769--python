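"""PCA and k-means segmentation of pixels by spectral similarity.

Pixels are the observations and features the variables: PCA score images
and k-means label images segment the tissue into regions of similar lipid
profile.  Both are fully deterministic — PCA fixes the loading sign so the
largest-magnitude element is positive, and k-means initialises from k
distinct pixels drawn with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from msilipid.preprocess import FeatureMatrix

__all__ = [
    "PCAResult",
    "ClusterResult",
    "pca",
    "kmeans",
    "cluster_center_spectra",
]


@dataclass
class PCAResult:
    scores: np.ndarray  # pixels x components
    loadings: np.ndarray  # features x components
    explained_variance_fraction: np.ndarray  # per component, non-increasing


@dataclass
class ClusterResult:
    labels: np.ndarray  # one int in [1, k] per pixel
    centers: np.ndarray  # k x features
    k: int
    seed: int
    inertia_history: np.ndarray  # within-cluster SS after each assignment
    empty_clusters: tuple[int, ...] = ()


def _as_pixel_matrix(data: FeatureMatrix | np.ndarray) -> np.ndarray:
    """features x pixels -> pixels x features observation matrix."""
    x = data.intensities if isinstance(data, FeatureMatrix) else np.asarray(data)
    return x.T


def pca(data: FeatureMatrix | np.ndarray, n_components: int = 5) -> PCAResult:
    """SVD-based PCA of an already centered/scaled matrix.

    *data* is features x pixels (rows centered across pixels).  Scores are
    the pixel projections, loadings the right singular vectors; explained
    fractions are singular values squared over the total.
    """
    x = _as_pixel_matrix(data)
    max_rank = min(x.shape)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for a {x.shape} matrix"
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("matrix is identically zero; PCA undefined")
    loadings = vt[:n_components].T  # features x components
    scores = u[:, :n_components] * s[:n_components]
    # deterministic sign: largest-|.| element of each loading is positive
    for c in range(n_components):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
            scores[:, c] = -scores[:, c]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=s[:n_components] ** 2 / total,
    )


def kmeans(
    data: FeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 10,
) -> ClusterResult:
    """Lloyd's algorithm on pixel vectors with seeded initialisation.

    Each of *n_init* restarts initialises its centers from k distinct
    pixels chosen by the seeded generator; the restart with the lowest
    final within-cluster sum of squares wins.  Iteration stops when no
    center moves more than *tol* or after *max_iter* rounds.  Identical
    seed and data give identical output.
    """
    x = _as_pixel_matrix(data)
    n_pixels = x.shape[0]
    if not 1 <= k <= n_pixels:
        raise ValueError(f"k must be in [1, {n_pixels}], got {k}")
    if n_init < 1:
        raise ValueError(f"n_init must be >= 1, got {n_init}")
    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(n_init):
        result = _lloyd(
            x, x[rng.choice(n_pixels, size=k, replace=False)].copy(),
            k, seed, max_iter, tol,
        )
        if best is None or result.inertia_history[-1] < best.inertia_history[-1]:
            best = result
    return best


def _lloyd(
    x: np.ndarray, centers: np.ndarray, k: int, seed: int,
    max_iter: int, tol: float,
) -> ClusterResult:
    n_pixels = x.shape[0]
    inertia_history = []
    labels = np.zeros(n_pixels, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(x, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        inertia_history.append(float(d2[np.arange(n_pixels), labels].sum()))
        new_centers = centers.copy()
        for c in range(k):
            members = labels == c
            if members.any():
                new_centers[c] = x[members].mean(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    d2 = cdist(x, centers, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    inertia_history.append(float(d2[np.arange(n_pixels), labels].sum()))
    empty = tuple(
        c + 1 for c in range(k) if not np.any(labels == c)
    )
    # final centers = exact member means (empty clusters keep position)
    for c in range(k):
        members = labels == c
        if members.any():
            centers[c] = x[members].mean(axis=0)
    return ClusterResult(
        labels=labels + 1,
        centers=centers,
        k=k,
        seed=seed,
        inertia_history=np.array(inertia_history),
        empty_clusters=empty,
    )


def cluster_center_spectra(
    result: ClusterResult, features: list
) -> pd.DataFrame:
    """Long table of cluster-center spectra: (cluster, feature m/z, intensity).

    Empty clusters are emitted with zero intensity and flagged.
    """
    rows = []
    for c in range(result.k):
        cluster = c + 1
        empty = cluster in result.empty_clusters
        for f, value in zip(features, result.centers[c]):
            rows.append(
                {
                    "cluster": cluster,
                    "mz": f.mz,
                    "intensity": 0.0 if empty else float(value),
                    "is_empty": empty,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "mz", "intensity", "is_empty"])
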