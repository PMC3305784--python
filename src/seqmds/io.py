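"""FASTA ingestion, exact deduplication, and in-/out-of-sample splitting.

Reads are nucleotide strings over ``{A, C, G, T, N}`` (case-insensitive on
input, stored uppercase).  An optional ``family=<int>`` token in the FASTA
header carries a ground-truth family label, used only when evaluating
against synthetic data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .errors import FastaParseError, ValidationError

VALID_RESIDUES = frozenset("ACGTN")

_FAMILY_TOKEN = re.compile(r"\bfamily=(\d+)\b")


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence read.

    Attributes
    ----------
    id:
        Unique identifier (first whitespace-delimited header token).
    residues:
        Uppercase nucleotide string over ``{A, C, G, T, N}``, length >= 1.
    truth_label:
        Optional integer family label parsed from a ``family=<int>``
        header token; ``None`` when absent.
    """

    id: str
    residues: str
    truth_label: Optional[int] = None


@dataclass(frozen=True)
class SampleSplit:
    """Partition of record indices into in-sample (size M) and out-of-sample sets.

    The in-sample subset is the part embedded by full MDS; the remainder is
    placed later by interpolation.  Both index arrays are sorted ascending
    so downstream stages preserve original collection order.
    """

    in_sample: np.ndarray
    out_of_sample: np.ndarray
    seed: int

    def __post_init__(self):
        n = len(self.in_sample) + len(self.out_of_sample)
        combined = np.concatenate([self.in_sample, self.out_of_sample])
        if not np.array_equal(np.sort(combined), np.arange(n)):
            raise ValidationError(
                "in_sample and out_of_sample must be disjoint and cover 0..N-1"
            )

    @property
    def n_total(self) -> int:
        return len(self.in_sample) + len(self.out_of_sample)

    @property
    def m_in_sample(self) -> int:
        return len(self.in_sample)


def _validate_residues(seq: str, record_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValidationError(
            f"record '{record_id}': invalid residue character(s) "
            f"{sorted(bad)!r}; allowed alphabet is A,C,G,T,N"
        )
    return seq


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved, residues are uppercased, and multi-line sequence
    bodies are concatenated.  Blank lines are permitted between entries.

    Raises
    ------
    FastaParseError
        If a sequence line precedes the first header (carries line number).
    ValidationError
        On invalid residue characters, empty records, or duplicate ids.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen_ids: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        tokens = header.split()
        if not tokens:
            raise FastaParseError("header line '>' has no identifier", header_line)
        rec_id = tokens[0]
        if rec_id in seen_ids:
            raise ValidationError(f"duplicate record id '{rec_id}'")
        seen_ids.add(rec_id)
        residues = _validate_residues("".join(chunks), rec_id)
        if not residues:
            raise ValidationError(f"record '{rec_id}' has an empty sequence")
        m = _FAMILY_TOKEN.search(header)
        label = int(m.group(1)) if m else None
        records.append(SequenceRecord(rec_id, residues, label))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        "sequence data before first '>' header", lineno
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as FASTA; truth labels ride as ``family=<int>`` tokens."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.truth_label is not None:
                fh.write(f">{rec.id} family={rec.truth_label}\n")
            else:
                fh.write(f">{rec.id}\n")
            for start in range(0, len(rec.residues), width):
                fh.write(rec.residues[start : start + width] + "\n")


def deduplicate(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Remove exact full-length residue duplicates, keeping first occurrence.

    Returns
    -------
    unique:
        Records whose residue strings are pairwise distinct, in input order.
    duplicate_map:
        Maps each removed record's id to the id of the kept representative,
        so labels assigned to representatives can be propagated back.
    """
    if not records:
        raise ValidationError("deduplicate requires a nonempty record list")
    kept: dict[str, str] = {}  # residues -> kept id
    unique: list[SequenceRecord] = []
    duplicate_map: dict[str, str] = {}
    for rec in records:
        if rec.residues in kept:
            duplicate_map[rec.id] = kept[rec.residues]
        else:
            kept[rec.residues] = rec.id
            unique.append(rec)
    return unique, duplicate_map


def split_sample(n_total: int, m_in_sample: int, seed: int) -> SampleSplit:
    """Uniformly random in-/out-of-sample partition, reproducible from seed."""
    if not 1 <= m_in_sample <= n_total:
        raise ValidationError(
            f"m_in_sample must satisfy 1 <= M <= N; got M={m_in_sample}, N={n_total}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    return SampleSplit(
        in_sample=np.sort(perm[:m_in_sample]),
        out_of_sample=np.sort(perm[m_in_sample:]),
        seed=seed,
    )
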