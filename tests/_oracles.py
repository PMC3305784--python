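"""Independent reference implementations used only by tests.

Each oracle recomputes a quantity by a route structurally different from
the package implementation (exhaustive enumeration, direct double loops,
closed forms) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment as a list of (char_a, char_b) columns.

    Gap columns carry '-'; the (-,-) column is structurally excluded.
    """
    if not a and not b:
        yield []
        return
    if a and b:
        for rest in enumerate_global_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest
    if a:
        for rest in enumerate_global_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_global_alignments(a, b[1:]):
            yield [("-", b[0])] + rest


def score_alignment_columns(cols, match, mismatch, gap_open, gap_extend) -> int:
    """Score a column list: affine gap runs cost open + len * extend."""
    score = 0
    gap_in_a = gap_in_b = False  # was the previous column a gap in a / in b?
    for x, y in cols:
        if x == "-":
            score -= gap_extend + (0 if gap_in_a else gap_open)
            gap_in_a, gap_in_b = True, False
        elif y == "-":
            score -= gap_extend + (0 if gap_in_b else gap_open)
            gap_in_a, gap_in_b = False, True
        else:
            score += match if (x == y and x != "N") else mismatch
            gap_in_a = gap_in_b = False
    return score


def brute_force_alignment_score(a, b, match, mismatch, gap_open, gap_extend) -> int:
    """Maximum score over an exhaustive enumeration of all global alignments."""
    return max(
        score_alignment_columns(cols, match, mismatch, gap_open, gap_extend)
        for cols in enumerate_global_alignments(a, b)
    )


def pair_counting_ari(labels_a, labels_b) -> float:
    """ARI from explicit enumeration of all item pairs."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    n = len(labels_a)
    ss = sd = ds = dd = 0  # same/different in a x same/different in b
    for i in range(n):
        for j in range(i + 1, n):
            sa = labels_a[i] == labels_a[j]
            sb = labels_b[i] == labels_b[j]
            if sa and sb:
                ss += 1
            elif sa:
                sd += 1
            elif sb:
                ds += 1
            else:
                dd += 1
    denom = (ss + sd) * (sd + dd) + (ss + ds) * (ds + dd)
    if denom == 0:
        return 1.0  # both partitions trivial (all-same or all-singleton)
    return 2.0 * (ss * dd - sd * ds) / denom


def exhaustive_kmedoids_cost(d: np.ndarray, n_clusters: int) -> float:
    """Global-optimum total cost over all medoid subsets of the given size."""
    n = d.shape[0]
    best = np.inf
    for combo in itertools.combinations(range(n), n_clusters):
        cost = d[:, combo].min(axis=1).sum()
        best = min(best, cost)
    return float(best)


def direct_guttman_product(delta: np.ndarray, coords: np.ndarray, eps=1e-10):
    """Explicit double-loop B-matrix assembly followed by a dense product."""
    n = coords.shape[0]
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dij = np.linalg.norm(coords[i] - coords[j])
            b[i, j] = -delta[i, j] / max(dij, eps)
    for i in range(n):
        b[i, i] = -b[i].sum()
    return b @ coords / n


def direct_stress(delta: np.ndarray, coords: np.ndarray) -> float:
    """Plain double-loop stress summation."""
    n = coords.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dij = np.linalg.norm(coords[i] - coords[j])
            total += (delta[i, j] - dij) ** 2
    return total
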