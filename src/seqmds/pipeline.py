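"""End-to-end orchestration of the full and interpolative pipelines.

Full pipeline: read -> deduplicate -> all-pairs NW distances -> SMACOF ->
k-medoids -> points file; exactly N(N-1)/2 alignments over the N unique
reads.  Interpolative pipeline: read -> deduplicate -> split (M in-sample)
-> in-sample distances + SMACOF + k-medoids -> per-point interpolation ->
label propagation -> points file; exactly M(M-1)/2 + (N-M)*M alignments.
Every stage is seeded and single-threaded-deterministic, so a run manifest
(config snapshot + seeds + counts) suffices to reproduce the points file
bitwise.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .align import AlignmentParams, build_distance_matrix
from .cluster import assign_interpolated_labels, kmedoids_cluster
from .errors import FormatError, PipelineError, ValidationError
from .interpolate import InterpolationParams, run_interpolation
from .io import read_fasta, deduplicate, split_sample
from .ledger import CostLedger
from .mds import EmbeddingConfiguration, MdsParams, run_smacof


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on, seeds included."""

    input_fasta: str
    output_dir: str
    mode: str = "full"  # "full" | "interpolative"
    m_in_sample: Optional[int] = None
    n_clusters: int = 3
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    mds: MdsParams = field(default_factory=MdsParams)
    interpolation: InterpolationParams = field(default_factory=InterpolationParams)
    split_seed: int = 0
    cluster_seed: int = 0
    n_workers: int = 1

    def __post_init__(self):
        if self.mode not in ("full", "interpolative"):
            raise ValidationError(f"unknown mode '{self.mode}'")
        if self.mode == "interpolative" and self.m_in_sample is None:
            raise ValidationError("interpolative mode requires m_in_sample")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["alignment"] = AlignmentParams(**d.get("alignment", {}))
        d["mds"] = MdsParams(**d.get("mds", {}))
        d["interpolation"] = InterpolationParams(**d.get("interpolation", {}))
        return cls(**d)


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient for bitwise reproduction."""

    config: dict
    n_input: int
    n_unique: int
    m_in_sample: Optional[int]
    ledger: dict
    final_stress: float
    normalized_stress: float
    points_path: str
    manifest_path: str
    wall_time_s: float

    def write(self) -> None:
        with open(self.manifest_path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def load_manifest(path) -> RunManifest:
    with open(path) as fh:
        return RunManifest(**json.load(fh))


def write_points_file(
    embedding: EmbeddingConfiguration, labels: Optional[np.ndarray], path
) -> None:
    """TSV rows ``index x y z label``, 6 significant digits, 0-based index.

    Embeddings with fewer than 3 dimensions are zero-padded to 3 so 3D
    point-cloud viewers always parse; labels may be omitted (written -1).
    """
    n = embedding.n
    if labels is None:
        labels = np.full(n, -1, dtype=np.int64)
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValidationError("labels length does not match embedding rows")
    if embedding.n_components > 3:
        raise ValidationError("points file supports at most 3 dimensions")
    coords = np.zeros((n, 3))
    coords[:, : embedding.n_components] = embedding.coords
    with open(path, "w") as fh:
        fh.write("# index\tx\ty\tz\tlabel\n")
        for i in range(n):
            x, y, z = coords[i]
            fh.write(f"{i}\t{x:.6g}\t{y:.6g}\t{z:.6g}\t{int(labels[i])}\n")


def read_points_file(path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a points file -> (n x 3 coords, labels)."""
    coords = []
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"points file line {lineno}: expected 5 fields")
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            labels.append(int(parts[4]))
    return (
        np.array(coords, dtype=np.float64).reshape(len(coords), 3),
        np.array(labels, dtype=np.int64),
    )


def _stage(name: str):
    """Context-free helper: wrap a stage body, naming the stage on failure."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def _cleanup(paths: list[Path]) -> None:
    for p in paths:
        try:
            p.unlink()
        except FileNotFoundError:
            pass


def run_full_pipeline(config: PipelineConfig) -> RunManifest:
    """Figures-of-merit pipeline over the entire (deduplicated) sample."""
    if config.mode != "full":
        raise ValidationError("run_full_pipeline requires mode='full'")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    points_path = out_dir / "points.tsv"
    manifest_path = out_dir / "manifest.json"
    ledger = CostLedger()
    t0 = time.perf_counter()
    try:
        with _stage("read"):
            records = read_fasta(config.input_fasta)
        with _stage("deduplicate"):
            unique, _dupmap = deduplicate(records)
        with _stage("distance"):
            delta = build_distance_matrix(
                unique, config.alignment, ledger, n_workers=config.n_workers
            )
        with _stage("mds"):
            mds_result = run_smacof(delta, config.mds, ledger)
        with _stage("cluster"):
            assignment = kmedoids_cluster(delta, config.n_clusters, config.cluster_seed)
        with _stage("write"):
            write_points_file(mds_result.embedding, assignment.labels, points_path)
    except PipelineError:
        _cleanup([points_path, manifest_path])
        raise
    manifest = RunManifest(
        config=config.as_dict(),
        n_input=len(records),
        n_unique=len(unique),
        m_in_sample=None,
        ledger=ledger.as_dict(),
        final_stress=mds_result.final_stress,
        normalized_stress=mds_result.normalized_stress,
        points_path=str(points_path),
        manifest_path=str(manifest_path),
        wall_time_s=time.perf_counter() - t0,
    )
    manifest.write()
    return manifest


def run_interpolative_pipeline(config: PipelineConfig) -> RunManifest:
    """Scaled-up pipeline: full MDS on M in-sample reads, interpolate the rest."""
    if config.mode != "interpolative":
        raise ValidationError("run_interpolative_pipeline requires mode='interpolative'")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    points_path = out_dir / "points.tsv"
    manifest_path = out_dir / "manifest.json"
    ledger = CostLedger()
    t0 = time.perf_counter()
    try:
        with _stage("read"):
            records = read_fasta(config.input_fasta)
        with _stage("deduplicate"):
            unique, _dupmap = deduplicate(records)
        n = len(unique)
        m = config.m_in_sample
        with _stage("split"):
            if not (m and 1 <= m < n):
                raise ValidationError(
                    f"interpolative mode requires 1 <= M < N; got M={m}, N={n}"
                )
            split = split_sample(n, m, config.split_seed)
            in_records = [unique[i] for i in split.in_sample]
            out_records = [unique[i] for i in split.out_of_sample]
        with _stage("distance"):
            delta_in = build_distance_matrix(
                in_records, config.alignment, ledger, n_workers=config.n_workers
            )
        with _stage("mds"):
            mds_result = run_smacof(delta_in, config.mds, ledger)
        with _stage("cluster"):
            assignment = kmedoids_cluster(delta_in, config.n_clusters, config.cluster_seed)
        with _stage("interpolate"):
            combined, _points = run_interpolation(
                mds_result.embedding,
                in_records,
                out_records,
                config.alignment,
                config.interpolation,
                ledger,
                n_workers=config.n_workers,
            )
        with _stage("label"):
            labels_combined = assign_interpolated_labels(
                assignment, mds_result.embedding, combined
            )
        with _stage("write"):
            # restore original (post-dedup) collection order
            order = np.concatenate([split.in_sample, split.out_of_sample])
            inverse = np.argsort(order, kind="stable")
            reordered = EmbeddingConfiguration(
                ids=[combined.ids[i] for i in inverse],
                coords=combined.coords[inverse],
            )
            write_points_file(reordered, labels_combined[inverse], points_path)
    except PipelineError:
        _cleanup([points_path, manifest_path])
        raise
    manifest = RunManifest(
        config=config.as_dict(),
        n_input=len(records),
        n_unique=n,
        m_in_sample=m,
        ledger=ledger.as_dict(),
        final_stress=mds_result.final_stress,
        normalized_stress=mds_result.normalized_stress,
        points_path=str(points_path),
        manifest_path=str(manifest_path),
        wall_time_s=time.perf_counter() - t0,
    )
    manifest.write()
    return manifest


def run_pipeline(config: PipelineConfig) -> RunManifest:
    if config.mode == "full":
        return run_full_pipeline(config)
    return run_interpolative_pipeline(config)


def rerun_from_manifest(path) -> RunManifest:
    """Re-execute a run from its manifest; output is bitwise identical."""
    manifest = load_manifest(path)
    config = PipelineConfig.from_dict(manifest.config)
    return run_pipeline(config)
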