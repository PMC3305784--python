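"""Clustering on the distance matrix and quantitative embedding comparison.

k-medoids (PAM) consumes the genetic-distance matrix directly, so no
coordinates are needed to cluster; labels for interpolated points are then
propagated through embedded space (nearest medoid, Euclidean), which costs
no additional alignments.  Agreement between labelings is measured by the
adjusted Rand index and between configurations by Procrustes RMSD, the
quantitative stand-ins for visual side-by-side comparison of full and
interpolated embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .align import DistanceMatrix
from .errors import ValidationError
from .mds import EmbeddingConfiguration


@dataclass
class ClusterAssignment:
    """Labels in [0, C) plus the C medoid record indices (label c == medoid c)."""

    labels: np.ndarray
    medoid_indices: np.ndarray
    n_clusters: int


@dataclass(frozen=True)
class ProcrustesReport:
    """Residual after the optimal similarity transform (rotation, reflection,
    translation, uniform scale) of one configuration onto another.

    Both configurations are standardized to unit Frobenius norm before
    superposition, so ``rmsd`` is scale-free and symmetric in its
    arguments; ``disparity`` is the total squared residual (``n * rmsd^2``)
    and ``scale`` is the raw factor that maps the second configuration
    onto the first.
    """

    rmsd: float
    scale: float
    disparity: float


def _total_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def kmedoids_cluster(delta: DistanceMatrix, n_clusters: int, seed: int = 0) -> ClusterAssignment:
    """PAM: greedy BUILD, then SWAP until no exchange lowers total cost.

    Both phases break ties toward lower indices, making the algorithm fully
    deterministic; the seed argument is accepted for interface stability
    but does not influence the result.
    """
    del seed
    n = delta.n
    if not 2 <= n_clusters <= n:
        raise ValidationError(f"n_clusters must satisfy 2 <= C <= n; got C={n_clusters}, n={n}")
    d = np.asarray(delta.values, dtype=np.float64)

    # BUILD: seed with the 1-medoid minimizer, then greedily add the point
    # with the largest cost reduction.
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < n_clusters:
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, d[:, best])

    # SWAP: steepest-descent exchanges.
    cost = _total_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best_cost = cost
        best_swap = None
        medoid_set = set(medoids)
        for mi in range(len(medoids)):
            others = [m for j, m in enumerate(medoids) if j != mi]
            rest = d[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in medoid_set:
                    continue
                new_cost = float(np.minimum(rest, d[:, h]).sum())
                if new_cost < best_cost - 1e-12:
                    best_cost = new_cost
                    best_swap = (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            cost = best_cost
            improved = True

    medoid_arr = np.array(medoids, dtype=np.int64)
    labels = np.argmin(d[:, medoid_arr], axis=1).astype(np.int64)
    labels[medoid_arr] = np.arange(n_clusters)  # a medoid always owns its cluster
    return ClusterAssignment(labels=labels, medoid_indices=medoid_arr, n_clusters=n_clusters)


def assign_interpolated_labels(
    assignment: ClusterAssignment,
    in_embedding: EmbeddingConfiguration,
    full_embedding: EmbeddingConfiguration,
) -> np.ndarray:
    """Propagate in-sample cluster labels to every row of the full embedding.

    In-sample rows (matched by id) keep their assigned labels; every other
    row takes the label of the nearest medoid in embedded Euclidean space.
    """
    if in_embedding.n_components != full_embedding.n_components:
        raise ValidationError("embedding dimensionality mismatch")
    if assignment.labels.shape[0] != in_embedding.n:
        raise ValidationError("assignment does not cover the in-sample embedding")
    in_index = {rid: i for i, rid in enumerate(in_embedding.ids)}
    medoid_coords = in_embedding.coords[assignment.medoid_indices]
    labels = np.empty(full_embedding.n, dtype=np.int64)
    for row, rid in enumerate(full_embedding.ids):
        if rid in in_index:
            labels[row] = assignment.labels[in_index[rid]]
        else:
            dist = np.linalg.norm(medoid_coords - full_embedding.coords[row], axis=1)
            labels[row] = int(np.argmin(dist))
    return labels


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement; 1 = identical, ~0 = independent."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValidationError("labelings must have equal length")
    if labels_a.size < 2:
        raise ValidationError("need at least 2 items to compare partitions")
    return float(adjusted_rand_score(labels_a, labels_b))


def procrustes_compare(
    x: EmbeddingConfiguration, y: EmbeddingConfiguration
) -> ProcrustesReport:
    """Superimpose y onto x over similarity transforms and report RMSD.

    MDS output is determined only up to rotation, reflection, translation
    and (for stress on rescaled dissimilarities) uniform scale, so all four
    are optimized out before the residual is measured.  With both
    configurations standardized to unit Frobenius norm the minimized
    squared residual is ``1 - (sum of singular values)^2``.
    """
    if list(x.ids) != list(y.ids):
        raise ValidationError("configurations must share ids in identical order")
    if x.coords.shape != y.coords.shape:
        raise ValidationError("configurations must share shape")
    n = x.n
    xc = x.coords - x.coords.mean(axis=0)
    yc = y.coords - y.coords.mean(axis=0)
    xnorm = float(np.linalg.norm(xc))
    ynorm = float(np.linalg.norm(yc))
    if xnorm == 0.0 and ynorm == 0.0:
        return ProcrustesReport(rmsd=0.0, scale=1.0, disparity=0.0)
    if xnorm == 0.0 or ynorm == 0.0:
        # one configuration collapses to a point: full residual remains
        return ProcrustesReport(rmsd=float(np.sqrt(1.0 / n)), scale=1.0, disparity=1.0)
    xs = xc / xnorm
    ys = yc / ynorm
    s = np.linalg.svd(ys.T @ xs, compute_uv=False)
    disparity = max(1.0 - float(s.sum()) ** 2, 0.0)
    return ProcrustesReport(
        rmsd=float(np.sqrt(disparity / n)),
        scale=float(s.sum()) * xnorm / ynorm,
        disparity=disparity,
    )
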