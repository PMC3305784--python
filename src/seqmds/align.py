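"""Needleman-Wunsch global alignment with affine gaps and genetic distances.

The aligner is the Gotoh three-state dynamic program: a gap of length g
costs ``gap_open + g * gap_extend``, and end gaps are penalized (true
global alignment).  The genetic distance between two reads is

    delta = 1 - (identical aligned columns) / (alignment length),

i.e. one minus fractional identity over the full global alignment, gap
columns included in the length, giving values in [0, 1].  To make delta
deterministic the traceback tie-break order is fixed: diagonal > up
(gap in the second sequence) > left (gap in the first).

The inner DP runs as numba-compiled kernels (nogil) so all-pairs matrix
construction can be threaded; results are bitwise independent of block
size and worker count because every pair is computed independently.
"""

from __future__ import annotations

import struct
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .errors import FormatError, ValidationError
from .io import SequenceRecord
from .ledger import CostLedger

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "DistanceMatrix",
    "CostLedger",
    "nw_align",
    "genetic_distance",
    "build_distance_matrix",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_distance_matrix_tsv",
    "read_distance_matrix_tsv",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4  # N never matches anything, including another N
_NEG = -(1 << 40)  # effectively -infinity for int64 scores


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring scheme.

    Defaults are EDNAFULL-like magnitudes: match +5, mismatch -4,
    gap open 10, gap extend 4 (both penalties nonnegative; a gap of
    length g costs ``gap_open + g * gap_extend``).
    """

    match_score: int = 5
    mismatch_score: int = -4
    gap_open: int = 10
    gap_extend: int = 4

    def __post_init__(self):
        if self.match_score <= self.mismatch_score:
            raise ValidationError("match_score must exceed mismatch_score")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValidationError("require gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    """One optimal global alignment under the fixed tie-break order."""

    aligned_a: str
    aligned_b: str
    score: int
    n_match: int
    length: int


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise genetic distances in [0, 1].

    Values are stored as float32, matching the on-disk binary format so
    write/read round trips are exactly lossless.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        if n and not np.allclose(self.values, self.values.T, atol=1e-6):
            raise ValidationError("distance matrix must be symmetric")
        if n and np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if n and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)


def encode_sequence(residues: str) -> np.ndarray:
    """Map a residue string to the uint8 codes used by the DP kernels."""
    try:
        return np.fromiter(
            (_CODE[c] for c in residues), dtype=np.uint8, count=len(residues)
        )
    except KeyError as exc:
        raise ValidationError(f"invalid residue {exc.args[0]!r}") from None


@njit(cache=True, nogil=True)
def _gotoh_fill(a, b, match, mismatch, go, ge):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in b: consume a ("up")
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in a: consume b ("left")
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + i * ge)
    for j in range(1, m + 1):
        Iy[0, j] = -(go + j * ge)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            s = match if (ai == bj and ai != _N_CODE) else mismatch
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = best + s
            # open (from M or the other gap state) or extend a gap in b
            opn = M[i - 1, j]
            if Iy[i - 1, j] > opn:
                opn = Iy[i - 1, j]
            v = opn - go - ge
            if Ix[i - 1, j] - ge > v:
                v = Ix[i - 1, j] - ge
            Ix[i, j] = v
            # open or extend a gap in a
            opn = M[i, j - 1]
            if Ix[i, j - 1] > opn:
                opn = Ix[i, j - 1]
            v = opn - go - ge
            if Iy[i, j - 1] - ge > v:
                v = Iy[i, j - 1] - ge
            Iy[i, j] = v
    return M, Ix, Iy


@njit(cache=True, nogil=True)
def _traceback(a, b, M, Ix, Iy, match, mismatch, go, ge):  # pragma: no cover
    """Recover one optimal path; tie-break diagonal > up > left.

    Returns (acol, bcol, n_match, length, score) where acol/bcol hold
    0-based residue indices, -1 marking a gap column.
    """
    n = a.shape[0]
    m = b.shape[0]
    score = M[n, m]
    state = 0  # 0 = M (diagonal), 1 = Ix (up), 2 = Iy (left)
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2
    acol = np.empty(n + m, dtype=np.int64)
    bcol = np.empty(n + m, dtype=np.int64)
    pos = n + m
    n_match = 0
    i, j = n, m
    while i > 0 or j > 0:
        pos -= 1
        if state == 0:
            ai = a[i - 1]
            bj = b[j - 1]
            s = match if (ai == bj and ai != _N_CODE) else mismatch
            if ai == bj and ai != _N_CODE:
                n_match += 1
            acol[pos] = i - 1
            bcol[pos] = j - 1
            target = M[i, j] - s
            if M[i - 1, j - 1] == target:
                state = 0
            elif Ix[i - 1, j - 1] == target:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            acol[pos] = i - 1
            bcol[pos] = -1
            cur = Ix[i, j]
            if M[i - 1, j] - go - ge == cur:
                state = 0
            elif Ix[i - 1, j] - ge == cur:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            acol[pos] = -1
            bcol[pos] = j - 1
            cur = Iy[i, j]
            if M[i, j - 1] - go - ge == cur:
                state = 0
            elif Iy[i, j - 1] - ge == cur:
                state = 2
            else:
                state = 1
            j -= 1
    return acol[pos:], bcol[pos:], n_match, n + m - pos, score


@njit(cache=True, nogil=True)
def _align_stats(a, b, match, mismatch, go, ge):  # pragma: no cover - jitted
    M, Ix, Iy = _gotoh_fill(a, b, match, mismatch, go, ge)
    acol, bcol, n_match, length, score = _traceback(
        a, b, M, Ix, Iy, match, mismatch, go, ge
    )
    return score, n_match, length


@njit(cache=True, nogil=True)
def _pair_distances(flat, starts, lens, pi, pj, match, mismatch, go, ge, out):
    """Genetic distances for an explicit pair list (nogil kernel)."""  # pragma: no cover
    for t in range(pi.shape[0]):
        i = pi[t]
        j = pj[t]
        a = flat[starts[i] : starts[i] + lens[i]]
        b = flat[starts[j] : starts[j] + lens[j]]
        score, n_match, length = _align_stats(a, b, match, mismatch, go, ge)
        out[t] = 1.0 - n_match / length


def nw_align(
    a: str, b: str, params: Optional[AlignmentParams] = None
) -> PairwiseAlignment:
    """Optimal global alignment of two nucleotide strings.

    The returned score maximizes the affine-gap objective over all global
    alignments; the single returned traceback follows the fixed tie-break
    order diagonal > up > left so identity fractions are deterministic.
    """
    if params is None:
        params = AlignmentParams()
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    ca = encode_sequence(a.upper())
    cb = encode_sequence(b.upper())
    M, Ix, Iy = _gotoh_fill(
        ca, cb, params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    acol, bcol, n_match, length, score = _traceback(
        ca, cb, M, Ix, Iy, params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    au = a.upper()
    bu = b.upper()
    aligned_a = "".join(au[k] if k >= 0 else "-" for k in acol)
    aligned_b = "".join(bu[k] if k >= 0 else "-" for k in bcol)
    return PairwiseAlignment(aligned_a, aligned_b, int(score), int(n_match), int(length))


def genetic_distance(aln: PairwiseAlignment) -> float:
    """``1 - fractional identity`` over the full alignment length."""
    return 1.0 - aln.n_match / aln.length


def _encode_collection(records: Sequence[SequenceRecord]):
    lens = np.array([len(r.residues) for r in records], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)
    flat = np.empty(int(lens.sum()), dtype=np.uint8)
    for rec, s, l in zip(records, starts, lens):
        flat[s : s + l] = encode_sequence(rec.residues)
    return flat, starts, lens


def _run_pair_chunks(flat, starts, lens, pi, pj, params, n_workers, block_size):
    """Evaluate the pair list in fixed-size chunks, optionally threaded.

    Chunk boundaries depend only on block_size, and each pair is computed
    independently, so the output is bitwise identical for any worker count
    and any block size.
    """
    out = np.empty(len(pi), dtype=np.float64)
    bounds = list(range(0, len(pi), block_size)) + [len(pi)]
    args = (params.match_score, params.mismatch_score,
            params.gap_open, params.gap_extend)

    def work(lo, hi):
        _pair_distances(flat, starts, lens, pi[lo:hi], pj[lo:hi], *args, out[lo:hi])

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            futures = [
                pool.submit(work, lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:])
            ]
            for f in futures:
                f.result()
    else:
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            work(lo, hi)
    return out


def build_distance_matrix(
    records: Sequence[SequenceRecord],
    params: Optional[AlignmentParams] = None,
    ledger: Optional[CostLedger] = None,
    block_size: int = 4096,
    n_workers: int = 1,
) -> DistanceMatrix:
    """All-pairs genetic distance matrix; exactly n(n-1)/2 alignments.

    ``block_size`` partitions the pair list for (threaded) evaluation; the
    result is independent of both block size and worker count.
    """
    if params is None:
        params = AlignmentParams()
    n = len(records)
    if n < 2:
        raise ValidationError("need at least 2 records for a distance matrix")
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    ids = [r.id for r in records]
    if len(set(ids)) != n:
        raise ValidationError("record ids must be unique")
    flat, starts, lens = _encode_collection(records)
    iu, ju = np.triu_indices(n, k=1)
    pi = iu.astype(np.int64)
    pj = ju.astype(np.int64)
    try:
        dvec = _run_pair_chunks(flat, starts, lens, pi, pj, params, n_workers, block_size)
    except Exception as exc:  # identify the offending pair for diagnostics
        raise ValidationError(f"alignment failed while building matrix: {exc}") from exc
    values = np.zeros((n, n), dtype=np.float32)
    values[iu, ju] = dvec
    values[ju, iu] = dvec
    if ledger is not None:
        ledger.add_alignments(len(pi))
    return DistanceMatrix(ids=ids, values=values)


_MAGIC = b"DMAT"
_VERSION = 1


def write_distance_matrix(m: DistanceMatrix, path) -> None:
    """Binary .dmat: magic, version, n, id block, row-major float32 payload."""
    ids_blob = "\n".join(m.ids).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<II", _VERSION, m.n))
        fh.write(struct.pack("<I", len(ids_blob)))
        fh.write(ids_blob)
        fh.write(np.ascontiguousarray(m.values, dtype=np.float32).tobytes())


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a .dmat file; raises :class:`FormatError` on any inconsistency."""
    data = Path(path).read_bytes()
    if len(data) < 16 or data[:4] != _MAGIC:
        raise FormatError("not a .dmat file (bad magic)")
    version, n = struct.unpack("<II", data[4:12])
    if version != _VERSION:
        raise FormatError(f"unsupported .dmat version {version}")
    (ids_len,) = struct.unpack("<I", data[12:16])
    if len(data) < 16 + ids_len:
        raise FormatError("truncated id block")
    ids = data[16 : 16 + ids_len].decode("utf-8").split("\n") if ids_len else []
    if len(ids) != n:
        raise FormatError(f"header declares n={n} but id block holds {len(ids)} ids")
    payload = data[16 + ids_len :]
    if len(payload) != 4 * n * n:
        raise FormatError(
            f"payload holds {len(payload) // 4} floats, expected {n * n}"
        )
    values = np.frombuffer(payload, dtype="<f4").reshape(n, n).copy()
    return DistanceMatrix(ids=ids, values=values)


def write_distance_matrix_tsv(m: DistanceMatrix, path) -> None:
    """Human-readable TSV export with ids as header row and first column."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(m.ids) + "\n")
        for rid, row in zip(m.ids, m.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_distance_matrix_tsv(path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise FormatError("TSV matrix must start with an 'id' header column")
        ids = header[1:]
        rows = []
        row_ids = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if row_ids != ids:
        raise FormatError("TSV row ids do not match header ids")
    values = np.array(rows, dtype=np.float32)
    if values.shape != (len(ids), len(ids)):
        raise FormatError("TSV matrix is not square")
    return DistanceMatrix(ids=ids, values=values)
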