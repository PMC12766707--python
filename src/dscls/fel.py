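"""Free-energy landscape construction and conformational clustering.

The ensemble's CA covariance is diagonalized (PCA); frames projected onto the
first two principal components give a 2-D conformational map. Binned frame
density rho converts to a free-energy surface G = -kT ln(rho/rho_max), so the
most populated bin sits at G = 0 and empty bins are +inf. Conformations are
grouped by Ward hierarchical clustering of the 2-D projections with a
predefined cluster count, and the frame nearest each cluster centroid is the
cluster's representative structure — the conformation used downstream for
contact filtering and interaction detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import Conformation, Ensemble, EnsembleError
from .trajectory import iterative_mean_structure

__all__ = [
    "PCAModel",
    "FELGrid",
    "ConformationClusters",
    "fit_pca",
    "build_fel",
    "cluster_conformations",
    "representative_conformations",
]


@dataclass(frozen=True)
class PCAModel:
    mean_coordinates: np.ndarray  # (3R,)
    eigenvalues: np.ndarray  # descending, A^2
    eigenvectors: np.ndarray  # (3R, m) orthonormal columns
    projected: np.ndarray  # (F, 2)

    @property
    def n_frames(self) -> int:
        return self.projected.shape[0]


@dataclass(frozen=True)
class FELGrid:
    bin_edges_pc1: np.ndarray
    bin_edges_pc2: np.ndarray
    counts: np.ndarray  # 2D int
    free_energy: np.ndarray  # 2D, k_BT units, min 0, empty = +inf
    temperature: float


@dataclass(frozen=True)
class ConformationClusters:
    n_clusters: int
    labels: np.ndarray  # per-frame cluster id
    centroids: np.ndarray  # (n_clusters, 2)
    representatives: np.ndarray  # cluster -> frame index


def fit_pca(ensemble: Ensemble) -> PCAModel:
    """PCA of superposed CA coordinates.

    Frames are superposed onto the iterative mean, flattened to 3R-vectors,
    and the covariance (ddof=1) eigendecomposed via SVD. Eigenvector signs
    follow the convention that each vector's largest-magnitude component is
    positive, which removes the arbitrary global sign per PC.
    """
    if not ensemble.is_calpha_only():
        raise EnsembleError("PCA expects a CA-only ensemble; call select_calpha first")
    if ensemble.n_frames < 3:
        raise EnsembleError("PCA needs at least 3 frames")
    sup, mean = iterative_mean_structure(ensemble.coordinates)
    F = ensemble.n_frames
    X = sup.reshape(F, -1)
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (F - 1)
    eigvecs = Vt.T
    # sign convention: largest-|component| of each eigenvector is positive
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(eigvecs.shape[1])])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    projected = Xc @ eigvecs[:, :2]
    return PCAModel(
        mean_coordinates=mu,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        projected=projected,
    )


def build_fel(pca: PCAModel, bins: int = 50, temperature: float = 300.15) -> FELGrid:
    """Bin the 2-D projection and convert density to free energy (k_BT units).

    G(bin) = -ln(count/max_count); the most populated bin is exactly 0 and
    empty bins carry a +inf sentinel. Temperature is recorded for callers
    converting to kJ/mol; the stored grid itself is in k_BT.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    pc1, pc2 = pca.projected[:, 0], pca.projected[:, 1]
    counts, ex, ey = np.histogram2d(pc1, pc2, bins=bins)
    counts = counts.astype(int)
    cmax = counts.max()
    with np.errstate(divide="ignore"):
        fe = np.where(counts > 0, -np.log(counts / cmax), np.inf)
    fe = np.where(counts > 0, np.maximum(fe, 0.0), np.inf)  # exact 0 at the mode
    return FELGrid(
        bin_edges_pc1=ex,
        bin_edges_pc2=ey,
        counts=counts,
        free_energy=fe,
        temperature=float(temperature),
    )


def cluster_conformations(pca: PCAModel, n_clusters: int = 5) -> ConformationClusters:
    """Ward-linkage hierarchical clustering of frames in (PC1, PC2).

    Cluster ids are relabeled by first-occurrence order so the result is
    independent of library internals; the representative of each cluster is
    its member frame nearest the centroid (ties to the lowest frame index).
    """
    from sklearn.cluster import AgglomerativeClustering

    F = pca.n_frames
    if not 1 <= n_clusters <= F:
        raise ValueError(f"n_clusters must be in [1, {F}]")
    if n_clusters == 1:
        raw = np.zeros(F, dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
        raw = model.fit_predict(pca.projected)
    # deterministic relabel: order of first appearance along the trajectory
    order: dict[int, int] = {}
    labels = np.empty(F, dtype=int)
    for f in range(F):
        c = int(raw[f])
        if c not in order:
            order[c] = len(order)
        labels[f] = order[c]
    centroids = np.vstack(
        [pca.projected[labels == c].mean(axis=0) for c in range(n_clusters)]
    )
    reps = np.empty(n_clusters, dtype=int)
    for c in range(n_clusters):
        members = np.where(labels == c)[0]
        d = np.linalg.norm(pca.projected[members] - centroids[c], axis=1)
        reps[c] = members[np.argmin(d)]  # argmin takes the first (lowest) index
    return ConformationClusters(
        n_clusters=n_clusters, labels=labels, centroids=centroids, representatives=reps
    )


def representative_conformations(
    ensemble: Ensemble, clusters: ConformationClusters
) -> list[Conformation]:
    """Extract the representative frame of each cluster, ordered by cluster id."""
    if len(clusters.labels) != ensemble.n_frames:
        raise EnsembleError(
            f"clusters cover {len(clusters.labels)} frames, ensemble has {ensemble.n_frames}"
        )
    return [ensemble.frame(int(f)) for f in clusters.representatives]
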