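"""Full metric MDS by iterative stress majorization (SMACOF).

Given an n x n matrix of target dissimilarities delta_ij, SMACOF seeks an
n x L configuration X minimizing the raw (unweighted Kruskal) stress

    sigma(X) = sum_{i<j} (delta_ij - d_ij(X))^2,

where d_ij(X) is the Euclidean distance between rows i and j.  Each
iteration applies the Guttman transform

    X' = (1/n) B(X) X,   b_ij = -delta_ij / max(d_ij(X), eps)  (i != j),
    b_ii = -sum_{j != i} b_ij,

which is guaranteed never to increase stress (majorization), so the
per-iteration stress trace is nonincreasing.  With uniform weights the
update is closed-form averaging and costs O(n^2 L) per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .align import DistanceMatrix
from .errors import DegenerateInputError, ValidationError
from .ledger import CostLedger

EPS_DISTANCE = 1e-10  # guard for coincident points in the B-matrix ratio


@dataclass(frozen=True)
class MdsParams:
    """SMACOF configuration.

    n_components is the embedding dimensionality L (3 for visual output);
    iteration stops when the relative stress change drops below
    ``tolerance`` or after ``max_iterations`` Guttman sweeps.

    init selects the starting configuration: ``"classical"`` (default)
    uses Torgerson classical scaling — deterministic, and for exactly
    embeddable dissimilarities it starts at the global optimum, avoiding
    the local minima a lone random start is prone to at small n;
    ``"random"`` draws i.i.d. uniform [-0.5, 0.5]^L coordinates from the
    seed (the seed is ignored by classical init).
    """

    n_components: int = 3
    max_iterations: int = 500
    tolerance: float = 1e-6
    seed: int = 0
    init: str = "classical"

    def __post_init__(self):
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.init not in ("classical", "random"):
            raise ValidationError("init must be 'classical' or 'random'")


@dataclass
class EmbeddingConfiguration:
    """n x L Cartesian coordinates with row-aligned record ids."""

    ids: list[str]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.ids):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {len(self.ids)} ids"
            )
        if len(self.ids) and not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class MdsResult:
    embedding: EmbeddingConfiguration
    final_stress: float
    normalized_stress: float
    n_iterations: int
    stress_trace: list[float] = field(default_factory=list)


def stress(delta: DistanceMatrix, x: EmbeddingConfiguration) -> float:
    """Raw stress sigma = sum over pairs of squared distance residuals."""
    if delta.n != x.n:
        raise ValidationError(
            f"distance matrix has {delta.n} rows but embedding has {x.n}"
        )
    d = pdist(x.coords)
    target = squareform(np.asarray(delta.values, dtype=np.float64), checks=False)
    return float(np.sum((target - d) ** 2))


def _guttman_update(target_sq: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """One Guttman transform on raw arrays (target_sq is the square-form delta)."""
    n = coords.shape[0]
    d = squareform(pdist(coords), checks=False)
    np.fill_diagonal(d, 1.0)  # diagonal ratio is irrelevant; avoid 0/0
    ratio = target_sq / np.maximum(d, EPS_DISTANCE)
    np.fill_diagonal(ratio, 0.0)
    b = -ratio
    np.fill_diagonal(b, ratio.sum(axis=1))
    return b.dot(coords) / n


def guttman_step(delta: DistanceMatrix, x: EmbeddingConfiguration) -> EmbeddingConfiguration:
    """Apply one majorization step; stress never increases."""
    if delta.n != x.n:
        raise ValidationError("dimension mismatch between delta and configuration")
    target = np.asarray(delta.values, dtype=np.float64)
    return EmbeddingConfiguration(ids=list(x.ids), coords=_guttman_update(target, x.coords))


def _classical_init(target: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson classical scaling: double-center squared dissimilarities
    and take the top-eigenvalue coordinates (negative eigenvalues clipped)."""
    n = target.shape[0]
    d2 = target.astype(np.float64) ** 2
    j = np.eye(n) - 1.0 / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    lam = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(lam)
    if coords.shape[1] < n_components:  # defensive; eigh returns n columns
        pad = np.zeros((n, n_components - coords.shape[1]))
        coords = np.hstack([coords, pad])
    return coords


def run_smacof(
    delta: DistanceMatrix,
    params: Optional[MdsParams] = None,
    ledger: Optional[CostLedger] = None,
) -> MdsResult:
    """Iterate the Guttman transform from a seeded random start to convergence.

    The stress trace records sigma at initialization and after every sweep;
    it is nonincreasing by the majorization guarantee.  Raises
    :class:`DegenerateInputError` when every off-diagonal dissimilarity is
    zero (the objective is then minimized by any single point and carries
    no geometry).
    """
    if params is None:
        params = MdsParams()
    n = delta.n
    if n < 2:
        raise ValidationError("need at least 2 items to embed")
    target = np.asarray(delta.values, dtype=np.float64)
    if not np.any(target[~np.eye(n, dtype=bool)]):
        raise DegenerateInputError(
            "all off-diagonal dissimilarities are zero; embedding is degenerate"
        )
    if params.init == "classical":
        coords = _classical_init(target, params.n_components)
    else:
        rng = np.random.default_rng(params.seed)
        coords = rng.uniform(-0.5, 0.5, size=(n, params.n_components))
    target_cond = squareform(target, checks=False)
    sum_sq = float(np.sum(target_cond**2))

    def raw_stress(c):
        return float(np.sum((target_cond - pdist(c)) ** 2))

    trace = [raw_stress(coords)]
    n_iter = 0
    for _ in range(params.max_iterations):
        coords = _guttman_update(target, coords)
        n_iter += 1
        sigma = raw_stress(coords)
        trace.append(sigma)
        prev = trace[-2]
        if prev == 0.0 or abs(prev - sigma) / prev < params.tolerance:
            break
    if ledger is not None:
        ledger.add_smacof_iterations(n_iter)
    embedding = EmbeddingConfiguration(ids=list(delta.ids), coords=coords)
    final = trace[-1]
    return MdsResult(
        embedding=embedding,
        final_stress=final,
        normalized_stress=final / sum_sq,
        n_iterations=n_iter,
        stress_trace=trace,
    )
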