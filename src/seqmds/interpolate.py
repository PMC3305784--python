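"""Out-of-sample MDS interpolation against a trained in-sample embedding.

Each out-of-sample read is placed by (1) computing its genetic distance to
every in-sample anchor on the fly (M Needleman-Wunsch alignments), (2)
keeping the k nearest anchors, and (3) running single-point stress
majorization against those fixed anchor coordinates:

    x <- (1/k) * sum_i [ p_i + (delta_i / max(d_i(x), eps)) * (x - p_i) ],

the one-free-point Guttman transform, so the per-point stress
sum_i (delta_i - d_i(x))^2 is nonincreasing across iterations.  In-sample
coordinates are never modified, and points are independent, so the total
alignment cost of an interpolative run is exactly M(M-1)/2 + (N-M)*M and
any processing order or chunking yields bitwise-identical output.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import AlignmentParams, _encode_collection, _pair_distances
from .errors import ValidationError
from .io import SequenceRecord
from .ledger import CostLedger
from .mds import EPS_DISTANCE, EmbeddingConfiguration

__all__ = [
    "InterpolationParams",
    "InterpolatedPoint",
    "anchor_distances",
    "select_anchors",
    "interpolate_point",
    "run_interpolation",
]


@dataclass(frozen=True)
class InterpolationParams:
    """Per-point majorization settings.

    k_neighbors anchors (nearest by genetic distance) enter the stress sum;
    iteration stops on relative stress change < tolerance or at
    max_iterations.  k may be set equal to M to use every anchor.
    """

    k_neighbors: int = 10
    max_iterations: int = 100
    tolerance: float = 1e-8

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class InterpolatedPoint:
    coords: np.ndarray
    anchor_indices: np.ndarray
    point_stress: float
    n_iterations: int
    stress_trace: list[float] = field(default_factory=list)


def anchor_distances(
    query: SequenceRecord,
    in_sample: Sequence[SequenceRecord],
    params: Optional[AlignmentParams] = None,
    ledger: Optional[CostLedger] = None,
) -> np.ndarray:
    """Genetic distance from one query to every in-sample anchor (M alignments)."""
    if params is None:
        params = AlignmentParams()
    m = len(in_sample)
    if m < 1:
        raise ValidationError("need at least one anchor")
    flat, starts, lens = _encode_collection([query, *in_sample])
    pi = np.zeros(m, dtype=np.int64)
    pj = np.arange(1, m + 1, dtype=np.int64)
    out = np.empty(m, dtype=np.float64)
    _pair_distances(
        flat, starts, lens, pi, pj,
        params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend, out,
    )
    if ledger is not None:
        ledger.add_alignments(m)
    return out


def select_anchors(distances: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest distances, ties broken by lower index."""
    distances = np.asarray(distances)
    if k > len(distances):
        raise ValidationError(f"k={k} exceeds the number of anchors {len(distances)}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    order = np.argsort(distances, kind="stable")
    return order[:k]


def _point_stress(x: np.ndarray, anchors: np.ndarray, deltas: np.ndarray) -> float:
    d = np.linalg.norm(x - anchors, axis=1)
    return float(np.sum((deltas - d) ** 2))


def interpolate_point(
    deltas: np.ndarray,
    anchors: np.ndarray,
    params: Optional[InterpolationParams] = None,
    ledger: Optional[CostLedger] = None,
    anchor_indices: Optional[np.ndarray] = None,
) -> InterpolatedPoint:
    """Place one point against k fixed anchors by stress majorization.

    A zero target distance short-circuits: the point is an exact duplicate
    of that anchor and inherits its coordinates.  Otherwise iteration
    starts from the anchor centroid (jittered if it coincides with an
    anchor whose target distance is nonzero).
    """
    if params is None:
        params = InterpolationParams()
    deltas = np.asarray(deltas, dtype=np.float64)
    anchors = np.asarray(anchors, dtype=np.float64)
    if not (np.all(np.isfinite(deltas)) and np.all(np.isfinite(anchors))):
        raise ValidationError("nonfinite anchor distances or coordinates")
    if anchors.ndim != 2 or anchors.shape[0] != deltas.shape[0]:
        raise ValidationError("anchors and deltas must agree in count")
    k = deltas.shape[0]
    if anchor_indices is None:
        anchor_indices = np.arange(k)

    if np.any(deltas == 0.0):
        hit = int(np.argmin(deltas))
        coords = anchors[hit].copy()
        return InterpolatedPoint(
            coords=coords,
            anchor_indices=np.asarray(anchor_indices),
            point_stress=_point_stress(coords, anchors, deltas),
            n_iterations=0,
            stress_trace=[],
        )

    x = anchors.mean(axis=0)
    d = np.linalg.norm(x - anchors, axis=1)
    if np.any(d < EPS_DISTANCE):
        x = x + 1e-9  # nudge off a coincident anchor before iterating
    trace = [_point_stress(x, anchors, deltas)]
    n_iter = 0
    for _ in range(params.max_iterations):
        d = np.maximum(np.linalg.norm(x - anchors, axis=1), EPS_DISTANCE)
        ratio = deltas / d
        x = np.mean(anchors + ratio[:, None] * (x - anchors), axis=0)
        n_iter += 1
        sigma = _point_stress(x, anchors, deltas)
        trace.append(sigma)
        prev = trace[-2]
        if prev == 0.0 or abs(prev - sigma) / prev < params.tolerance:
            break
    if ledger is not None:
        ledger.add_majorization_iterations(n_iter)
    return InterpolatedPoint(
        coords=x,
        anchor_indices=np.asarray(anchor_indices),
        point_stress=trace[-1],
        n_iterations=n_iter,
        stress_trace=trace,
    )


def run_interpolation(
    in_embedding: EmbeddingConfiguration,
    in_records: Sequence[SequenceRecord],
    out_records: Sequence[SequenceRecord],
    aln_params: Optional[AlignmentParams] = None,
    interp_params: Optional[InterpolationParams] = None,
    ledger: Optional[CostLedger] = None,
    n_workers: int = 1,
) -> tuple[EmbeddingConfiguration, list[InterpolatedPoint]]:
    """Embed every out-of-sample record into the trained configuration.

    Returns the combined embedding (in-sample rows first, unchanged,
    followed by one row per out-of-sample record in the given order) plus
    per-point diagnostics.  Out-of-sample points are mutually independent,
    so the result is identical for any processing order or worker count.
    """
    if aln_params is None:
        aln_params = AlignmentParams()
    if interp_params is None:
        interp_params = InterpolationParams()
    m = len(in_records)
    if in_embedding.n != m:
        raise ValidationError("in_embedding rows must correspond to in_records")
    if [r.id for r in in_records] != list(in_embedding.ids):
        raise ValidationError("in_embedding ids must match in_records ids in order")
    in_ids = {r.id for r in in_records}
    out_ids = [r.id for r in out_records]
    if in_ids & set(out_ids):
        raise ValidationError("id collision between in-sample and out-of-sample sets")
    if len(set(out_ids)) != len(out_ids):
        raise ValidationError("duplicate ids in out-of-sample set")
    if interp_params.k_neighbors > m:
        raise ValidationError(
            f"k_neighbors={interp_params.k_neighbors} exceeds in-sample size M={m}"
        )
    if not out_records:
        return (
            EmbeddingConfiguration(ids=list(in_embedding.ids), coords=in_embedding.coords.copy()),
            [],
        )

    anchors_coords = in_embedding.coords
    k = interp_params.k_neighbors
    results: list[Optional[InterpolatedPoint]] = [None] * len(out_records)

    def place(idx: int) -> InterpolatedPoint:
        dists = anchor_distances(out_records[idx], in_records, aln_params, ledger=None)
        sel = select_anchors(dists, k)
        return interpolate_point(
            dists[sel], anchors_coords[sel], interp_params,
            ledger=None, anchor_indices=sel,
        )

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            for idx, point in zip(range(len(out_records)), pool.map(place, range(len(out_records)))):
                results[idx] = point
    else:
        for idx in range(len(out_records)):
            results[idx] = place(idx)

    points = [p for p in results if p is not None]
    if ledger is not None:
        ledger.add_alignments(m * len(out_records))
        ledger.add_majorization_iterations(sum(p.n_iterations for p in points))
    coords = np.vstack([in_embedding.coords] + [p.coords[None, :] for p in points])
    ids = list(in_embedding.ids) + out_ids
    return EmbeddingConfiguration(ids=ids, coords=coords), points
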