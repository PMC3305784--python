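import numpy as np
import pytest

from seqmds import (
    AlignmentParams,
    FamilyGeneratorParams,
    build_distance_matrix,
    deduplicate,
    generate_families,
    generate_geometric,
)


@pytest.fixture(scope="session")
def aln_params():
    return AlignmentParams()


def unique_family_records(n_families, per_family, seed, margin=10):
    """Exactly n_families * per_family reads with pairwise-distinct residues.

    Generates with a member margin, strips duplicates, and keeps the first
    per_family unique members of each family — deterministic given seed.
    """
    params = FamilyGeneratorParams(
        n_families=n_families, members_per_family=per_family + margin, seed=seed
    )
    unique, _ = deduplicate(generate_families(params))
    counts: dict[int, int] = {}
    out = []
    for rec in unique:
        if counts.get(rec.truth_label, 0) < per_family:
            out.append(rec)
            counts[rec.truth_label] = counts.get(rec.truth_label, 0) + 1
    assert len(out) == n_families * per_family, "margin too small for uniqueness"
    return out


@pytest.fixture(scope="session")
def families_small():
    """3 families x 10 unique members, fixed seed."""
    return unique_family_records(3, 10, seed=0)


@pytest.fixture(scope="session")
def small_delta(families_small, aln_params):
    return build_distance_matrix(families_small, aln_params)


@pytest.fixture(scope="session")
def geom50():
    return generate_geometric(50, 3, seed=0)
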