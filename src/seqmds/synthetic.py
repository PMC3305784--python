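"""Synthetic inputs with known structure for every pipeline stage.

Two generators, two purposes:

* ``generate_families`` emulates an environmental amplicon read set:
  C well-separated ancestral sequences (< 200 nt), each expanded into a
  family by per-site substitutions and single-site indels, with optional
  verbatim duplicates.  Truth labels exercise end-to-end cluster recovery
  through the alignment stage.
* ``generate_geometric`` produces Gaussian blobs in R^L together with
  their exact Euclidean distance matrix — a perfectly embeddable instance
  whose true configuration is known, the oracle substrate for MDS and
  interpolation tests (sequence-derived distances have no known
  ground-truth embedding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .align import AlignmentParams, DistanceMatrix, genetic_distance, nw_align
from .errors import GenerationError, ValidationError
from .io import SequenceRecord

_BASES = np.array(list("ACGT"))
_MAX_RETRIES = 200


@dataclass(frozen=True)
class FamilyGeneratorParams:
    """Controls for the sequence-family generator.

    Rates are per site: each member of a family is its ancestor with
    substitutions at rate ``substitution_rate`` (to a uniformly chosen
    different base) and single-site indels at rate ``indel_rate`` (insert
    or delete with equal probability).  Ancestors are uniform random
    sequences, resampled until every pair is at least
    ``min_ancestor_distance`` apart in genetic distance.
    """

    n_families: int = 3
    members_per_family: Union[int, Sequence[int]] = 50
    ancestor_length_range: tuple[int, int] = (120, 180)
    substitution_rate: float = 0.02
    indel_rate: float = 0.005
    min_ancestor_distance: float = 0.30
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        lo, hi = self.ancestor_length_range
        if not 1 <= lo <= hi < 200:
            raise ValidationError("ancestor lengths must lie in [1, 200)")
        for name in ("substitution_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValidationError("duplicate_fraction must lie in [0, 1)")

    def family_sizes(self) -> list[int]:
        if isinstance(self.members_per_family, int):
            return [self.members_per_family] * self.n_families
        sizes = list(self.members_per_family)
        if len(sizes) != self.n_families:
            raise ValidationError("members_per_family list must have n_families entries")
        return sizes


@dataclass
class GeometricFixture:
    """Blobs in R^L with their exact (rescaled) Euclidean distance matrix."""

    true_coords: np.ndarray  # coordinates consistent with delta (already rescaled)
    delta: DistanceMatrix
    true_labels: np.ndarray
    scale: float  # divisor applied to raw distances to reach [0, 1]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, ancestor: str, sub_rate: float, indel_rate: float) -> str:
    out: list[str] = []
    for base in ancestor:
        r = rng.random()
        if r < indel_rate:
            if rng.random() < 0.5:
                out.append(_random_sequence(rng, 1) + base)  # insertion before site
            # else: deletion — site dropped
            continue
        if rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(base)
    seq = "".join(out)
    return seq if seq else ancestor[0]  # never emit an empty read


def _sample_ancestors(rng: np.random.Generator, params: FamilyGeneratorParams) -> list[str]:
    aln = AlignmentParams()
    for _ in range(_MAX_RETRIES):
        lo, hi = params.ancestor_length_range
        ancestors = [
            _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            for _ in range(params.n_families)
        ]
        ok = all(
            genetic_distance(nw_align(ancestors[i], ancestors[j], aln))
            >= params.min_ancestor_distance
            for i in range(params.n_families)
            for j in range(i + 1, params.n_families)
        )
        if ok:
            return ancestors
    raise GenerationError(
        f"could not sample {params.n_families} ancestors with pairwise distance "
        f">= {params.min_ancestor_distance} in {_MAX_RETRIES} attempts"
    )


def generate_families(params: Optional[FamilyGeneratorParams] = None) -> list[SequenceRecord]:
    """Generate labeled sequence families; fully reproducible from the seed."""
    if params is None:
        params = FamilyGeneratorParams()
    rng = np.random.default_rng(params.seed)
    ancestors = _sample_ancestors(rng, params)
    records: list[SequenceRecord] = []
    for fam, (ancestor, size) in enumerate(zip(ancestors, params.family_sizes())):
        for member in range(size):
            seq = _mutate(rng, ancestor, params.substitution_rate, params.indel_rate)
            records.append(SequenceRecord(f"f{fam}_m{member}", seq, truth_label=fam))
    n_dup = int(params.duplicate_fraction * len(records))
    if n_dup:
        sources = rng.choice(len(records), size=n_dup, replace=False)
        for t, src in enumerate(sources):
            rec = records[int(src)]
            records.append(
                SequenceRecord(f"{rec.id}_dup{t}", rec.residues, rec.truth_label)
            )
    return records


def generate_geometric(
    n: int,
    n_blobs: int,
    n_components: int = 3,
    blob_sd: float = 0.02,
    seed: int = 0,
) -> GeometricFixture:
    """Gaussian blobs with an exactly embeddable distance matrix.

    Blob centers are drawn uniformly in the unit cube and resampled until
    every pair is at least ``6 * blob_sd`` apart; raw Euclidean distances
    are divided by their maximum so delta lies in [0, 1], and the stored
    coordinates are divided by the same factor so delta remains their
    exact Euclidean distance matrix.
    """
    if not 1 <= n_blobs <= n:
        raise ValidationError("require 1 <= n_blobs <= n")
    rng = np.random.default_rng(seed)
    min_sep = 6.0 * blob_sd
    centers = None
    for _ in range(_MAX_RETRIES):
        cand = rng.uniform(0.0, 1.0, size=(n_blobs, n_components))
        if n_blobs == 1 or pdist(cand).min() >= min_sep:
            centers = cand
            break
    if centers is None:
        raise GenerationError(
            f"could not place {n_blobs} centers separated by {min_sep:g}"
        )
    labels = np.sort(np.arange(n) % n_blobs)
    coords = centers[labels] + rng.normal(0.0, blob_sd, size=(n, n_components))
    raw = squareform(pdist(coords))
    dmax = float(raw.max())
    scale = dmax if dmax > 0 else 1.0
    delta = DistanceMatrix(
        ids=[f"p{i}" for i in range(n)],
        values=(raw / scale).astype(np.float32),
    )
    return GeometricFixture(
        true_coords=coords / scale,
        delta=delta,
        true_labels=labels,
        scale=scale,
    )
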