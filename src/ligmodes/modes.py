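"""Binding-mode discovery from interaction fingerprints.

Frames with similar interaction patterns are grouped into binding modes:
pairwise Tanimoto (Jaccard) similarity over fingerprint rows gives the
similarity matrix; kMeans on the raw 0/1 vectors with the cluster number
selected by the mean Silhouette score gives the modes; the frame closest
to each cluster centroid is that mode's representative, and the mean
intra-cluster Tanimoto is its specificity (1 = perfectly conserved
interaction pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score

from .fingerprints import Fingerprint

__all__ = [
    "SimilarityMatrix",
    "ModeClustering",
    "tanimoto",
    "similarity_matrix",
    "cluster_binding_modes",
    "representative_frames",
    "cluster_specificity",
]


@dataclass
class SimilarityMatrix:
    """Symmetric frames × frames Tanimoto coefficients in [0, 1]."""

    values: np.ndarray
    frame_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not self.frame_ids:
            self.frame_ids = list(range(self.values.shape[0]))


@dataclass
class ModeClustering:
    """Result of Silhouette-selected kMeans over fingerprint rows."""

    k: int
    labels: np.ndarray
    silhouette_by_k: dict[int, float]
    representatives: list[int]
    specificity: list[float]
    sizes: list[int]
    frame_ids: list[int] = field(default_factory=list)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) coefficient of two boolean vectors:
    |a AND b| / |a OR b|; two all-zero vectors are identical patterns (1)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def similarity_matrix(fp: Fingerprint) -> SimilarityMatrix:
    """Pairwise Tanimoto over all fingerprint rows (vectorized)."""
    m = fp.matrix.astype(np.int64)
    if m.shape[0] < 1:
        raise ValueError("fingerprint has no frames")
    inter = m @ m.T
    counts = m.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return SimilarityMatrix(values, list(fp.frame_ids))


def _rows_all_identical(matrix: np.ndarray) -> bool:
    return bool(np.all(matrix == matrix[0]))


def cluster_binding_modes(
    fp: Fingerprint,
    k_min: int = 2,
    k_max: int = 10,
    n_init: int = 10,
    seed: int = 0,
    feature_space: str = "fingerprint",
) -> ModeClustering:
    """kMeans binding-mode clustering with Silhouette-selected k.

    ``k`` is the argmax of the mean Silhouette score (Euclidean, the same
    metric the clusterer uses) over ``k_min..min(k_max, frames-1)``; ties
    go to the smallest k.  All-identical rows are the degenerate one-mode
    case (k=1, specificity 1).  ``feature_space`` selects the clustered
    vectors: raw 0/1 fingerprint rows (default) or rows of the Tanimoto
    similarity matrix.
    """
    if fp.n_frames < 3:
        raise ValueError(f"need at least 3 frames to cluster, got {fp.n_frames}")
    if feature_space not in {"fingerprint", "similarity"}:
        raise ValueError(f"unknown feature space {feature_space!r}")
    sim = similarity_matrix(fp)
    if _rows_all_identical(fp.matrix):
        return ModeClustering(
            k=1,
            labels=np.zeros(fp.n_frames, dtype=int),
            silhouette_by_k={},
            representatives=[fp.frame_ids[0]],
            specificity=[1.0],
            sizes=[fp.n_frames],
            frame_ids=list(fp.frame_ids),
        )
    X = fp.matrix.astype(float) if feature_space == "fingerprint" else sim.values
    k_hi = min(k_max, fp.n_frames - 1)
    silhouettes: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in range(k_min, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        with warnings.catch_warnings():
            # duplicate binary rows legitimately yield < k distinct clusters
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        silhouettes[k] = float(silhouette_score(X, labels, metric="euclidean"))
        fits[k] = labels
    if not silhouettes:
        raise ValueError("no k in the search range produced >= 2 distinct clusters")
    best_k = min(silhouettes, key=lambda k: (-silhouettes[k], k))
    labels = fits[best_k]
    clustering = ModeClustering(
        k=best_k,
        labels=labels,
        silhouette_by_k=silhouettes,
        representatives=[],
        specificity=[],
        sizes=[int(np.sum(labels == c)) for c in range(best_k)],
        frame_ids=list(fp.frame_ids),
    )
    clustering.representatives = representative_frames(clustering, fp)
    clustering.specificity = cluster_specificity(clustering, sim)
    return clustering


def representative_frames(clustering: ModeClustering, fp: Fingerprint) -> list[int]:
    """Per-cluster frame id of the member closest (Euclidean) to the cluster
    centroid of the 0/1 rows; ties go to the lowest frame id."""
    reps: list[int] = []
    X = fp.matrix.astype(float)
    frame_ids = np.asarray(fp.frame_ids)
    for c in range(clustering.k):
        members = np.flatnonzero(clustering.labels == c)
        centroid = X[members].mean(axis=0)
        dist = np.linalg.norm(X[members] - centroid, axis=1)
        # argmin returns the first (lowest-index) minimum: the tie rule
        reps.append(int(frame_ids[members[int(np.argmin(dist))]]))
    return reps


def cluster_specificity(clustering: ModeClustering, sim: SimilarityMatrix) -> list[float]:
    """Mean off-diagonal intra-cluster Tanimoto per cluster (singleton → 1)."""
    out: list[float] = []
    for c in range(clustering.k):
        members = np.flatnonzero(clustering.labels == c)
        if len(members) < 2:
            out.append(1.0)
            continue
        block = sim.values[np.ix_(members, members)]
        n = len(members)
        off_diag_sum = float(block.sum() - np.trace(block))
        out.append(off_diag_sum / (n * (n - 1)))
    return out
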