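"""Optimal Gaussian-component estimation via spectral clustering.

The number of mixture components is chosen by clustering the
robust-scaled cohort for each candidate k, scoring every partition with
the Davies-Bouldin index, and keeping the best k.  The spectral embedding
uses the symmetric normalised graph Laplacian whose smallest eigenpairs
are obtained with the LOBPCG block eigensolver, which keeps the scan
cheap on cohorts with hundreds to thousands of patients.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import lobpcg
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingModel",
    "ClusterScan",
    "robust_scale_fit",
    "spectral_embed",
    "cluster_embedding",
    "davies_bouldin",
    "select_components",
]


@dataclass
class ScalingModel:
    """Per-feature robust standardisation: subtract median, divide by IQR.

    Features with zero interquartile range are flagged degenerate and
    centred only (scale 1), so constant columns survive the transform.
    """

    center: np.ndarray
    scale: np.ndarray
    degenerate_flags: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.center) / self.scale

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.scale + self.center

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "degenerate_flags": self.degenerate_flags.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingModel":
        return cls(
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            degenerate_flags=np.asarray(d["degenerate_flags"], dtype=bool),
        )


def robust_scale_fit(matrix: np.ndarray) -> ScalingModel:
    """Fit medians and interquartile ranges column-wise.

    Quartiles use the linear-interpolation convention.  Requires at least
    4 rows so that quartiles are defined.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 4:
        raise ValueError("robust scaling needs an n x d matrix with n >= 4")
    center = np.median(matrix, axis=0)
    q1, q3 = np.percentile(matrix, [25, 75], axis=0)
    iqr = q3 - q1
    degenerate = iqr == 0.0
    scale = np.where(degenerate, 1.0, iqr)
    return ScalingModel(center=center, scale=scale, degenerate_flags=degenerate)


def _affinity_matrix(
    scaled: np.ndarray,
    bandwidth: float | None = None,
    n_neighbors: int | None = None,
) -> sp.csr_matrix:
    """Gaussian-kernel affinity, sparsified to a symmetric m-NN graph.

    Bandwidth defaults to the median pairwise Euclidean distance; the
    neighbourhood size defaults to max(10, ceil(log2 n)).  Symmetrisation
    keeps an edge if either endpoint selected it.
    """
    n = scaled.shape[0]
    dists = squareform(pdist(scaled))
    if bandwidth is None:
        offdiag = dists[np.triu_indices(n, k=1)]
        bandwidth = float(np.median(offdiag))
    if bandwidth <= 0.0:
        bandwidth = 1.0  # all points identical; uniform affinity
    W = np.exp(-(dists**2) / (2.0 * bandwidth**2))
    np.fill_diagonal(W, 0.0)
    if n_neighbors is None:
        n_neighbors = max(10, math.ceil(math.log2(n)))
    m = min(n_neighbors, n - 1)
    # keep the m largest affinities per row, then symmetrise with max
    keep = np.zeros_like(W, dtype=bool)
    top = np.argpartition(-W, m - 1, axis=1)[:, :m]
    rows = np.repeat(np.arange(n), m)
    keep[rows, top.ravel()] = True
    keep |= keep.T
    W = np.where(keep, W, 0.0)
    return sp.csr_matrix(W)


def _normalized_laplacian(W: sp.csr_matrix) -> sp.csr_matrix:
    """Symmetric normalised Laplacian I - D^(-1/2) W D^(-1/2)."""
    n = W.shape[0]
    deg = np.asarray(W.sum(axis=1)).ravel()
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    Dh = sp.diags(inv_sqrt)
    return (sp.identity(n, format="csr") - Dh @ W @ Dh).tocsr()


def _smallest_eigenvectors(
    L: sp.csr_matrix,
    k: int,
    seed: int,
    tol: float = 1e-8,
    maxiter: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """k smallest eigenpairs of a symmetric Laplacian.

    LOBPCG with a Jacobi (diagonal) preconditioner and a seeded random
    orthonormal start; problems too small for a stable block iteration,
    or a non-converged run, fall back to a dense eigendecomposition.
    """
    n = L.shape[0]
    if n < 100 or k > n // 5:
        vals, vecs = scipy.linalg.eigh(L.toarray())
        return vals[:k], vecs[:, :k]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    X, _ = np.linalg.qr(X)
    diag = L.diagonal()
    inv_diag = np.where(np.abs(diag) > 1e-12, 1.0 / diag, 1.0)
    M = sp.diags(inv_diag)  # Jacobi preconditioner
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            vals, vecs = lobpcg(
                L, X, M=M, largest=False, tol=tol, maxiter=maxiter
            )
        except Exception:  # numerical breakdown: fall back to dense
            logger.warning("LOBPCG failed; falling back to dense eigensolver")
            vals, vecs = scipy.linalg.eigh(L.toarray())
            return vals[:k], vecs[:, :k]
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    residual = np.linalg.norm(L @ vecs - vecs * vals, axis=0)
    if np.any(residual > 1e-4):
        logger.warning("LOBPCG did not converge; falling back to dense eigensolver")
        dvals, dvecs = scipy.linalg.eigh(L.toarray())
        return dvals[:k], dvecs[:, :k]
    return vals, vecs


def spectral_embed(
    scaled: np.ndarray,
    k: int,
    bandwidth: float | None = None,
    n_neighbors: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Rows of the k smallest Laplacian eigenvectors, L2-normalised.

    Disconnected affinity graphs are legal: the zero eigenvalue then has
    multiplicity equal to the number of components and the embedding
    separates them exactly.
    """
    scaled = np.asarray(scaled, dtype=float)
    n = scaled.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n; got k={k}, n={n}")
    W = _affinity_matrix(scaled, bandwidth=bandwidth, n_neighbors=n_neighbors)
    L = _normalized_laplacian(W)
    _, vecs = _smallest_eigenvectors(L, k, seed=seed)
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return vecs / norms


def cluster_embedding(embedding: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means on the spectral embedding: greedy k-means++, 10 restarts."""
    embedding = np.asarray(embedding, dtype=float)
    if not np.isfinite(embedding).all():
        raise ValueError("embedding contains non-finite values")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(embedding)


def davies_bouldin(scaled: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst ratio
    (S_i + S_j) / M_ij of summed within-cluster scatter to centroid
    separation.  Lower values indicate more compact, better separated
    partitions.
    """
    scaled = np.asarray(scaled, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.stack([scaled[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array(
        [
            np.linalg.norm(scaled[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(uniq)
        ]
    )
    sep = squareform(pdist(centroids))
    offdiag = ~np.eye(k, dtype=bool)
    if np.any(sep[offdiag] == 0.0):
        raise ValueError("degenerate centroids: two clusters share a centroid")
    ratio = (scatter[:, None] + scatter[None, :]) / np.where(offdiag, sep, np.inf)
    return float(np.mean(ratio.max(axis=1)))


@dataclass
class ClusterScan:
    """Record of a Davies-Bouldin scan over candidate component counts."""

    k_min: int
    k_max: int
    rule: str  # "max" keeps the highest score, "min" the lowest
    patience: int
    entries: list[tuple[int, float, np.ndarray]] = field(default_factory=list)
    opt: int = 0
    terminated_early: bool = False

    def scores(self) -> list[tuple[int, float]]:
        return [(k, s) for k, s, _ in self.entries]

    def labels_for(self, k: int) -> np.ndarray:
        for kk, _, lab in self.entries:
            if kk == k:
                return lab
        raise KeyError(f"k={k} was not evaluated")

    def to_json(self) -> str:
        return json.dumps(
            {
                "k_range": [self.k_min, self.k_max],
                "rule": self.rule,
                "patience": self.patience,
                "entries": [
                    {"k": k, "dbs": s} for k, s, _ in self.entries
                ],
                "opt": self.opt,
                "terminated_early": self.terminated_early,
            },
            indent=2,
        )


def select_components(
    scaled: np.ndarray,
    k_range: tuple[int, int] = (2, 20),
    rule: str = "max",
    patience: int = 5,
    seed: int = 0,
    bandwidth: float | None = None,
    n_neighbors: int | None = None,
) -> ClusterScan:
    """Scan k ascending, score each spectral partition, keep the best.

    The affinity graph and its Laplacian eigenvectors do not depend on k,
    so they are computed once for k_max and each candidate k uses the
    leading k columns.  The scan stops early once ``patience`` consecutive
    candidates fail to improve the running best under ``rule`` (ties keep
    the smaller k).
    """
    scaled = np.asarray(scaled, dtype=float)
    n = scaled.shape[0]
    k_min, k_max = k_range
    if k_min > k_max:
        raise ValueError("empty k-range")
    if k_min < 2 or k_max >= n:
        raise ValueError(f"need 2 <= k_min <= k_max < n; got [{k_min}, {k_max}], n={n}")
    if rule not in ("max", "min"):
        raise ValueError("rule must be 'max' or 'min'")

    W = _affinity_matrix(scaled, bandwidth=bandwidth, n_neighbors=n_neighbors)
    L = _normalized_laplacian(W)
    _, vecs = _smallest_eigenvectors(L, k_max, seed=seed)

    scan = ClusterScan(k_min=k_min, k_max=k_max, rule=rule, patience=patience)
    best_score = -np.inf if rule == "max" else np.inf
    stale = 0
    for k in range(k_min, k_max + 1):
        emb = vecs[:, :k]
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        labels = cluster_embedding(emb / norms, k, seed=seed)
        try:
            score = davies_bouldin(scaled, labels)
        except ValueError:
            # degenerate partition at this k; record as worst possible
            score = -np.inf if rule == "max" else np.inf
        scan.entries.append((k, score, labels))
        improved = score > best_score if rule == "max" else score < best_score
        if improved:
            best_score = score
            scan.opt = k
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                scan.terminated_early = True
                break
    return scan
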