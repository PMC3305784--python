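import numpy as np
import pytest

from seqmds import (
    AlignmentParams,
    CostLedger,
    EmbeddingConfiguration,
    InterpolationParams,
    SequenceRecord,
    ValidationError,
    anchor_distances,
    interpolate_point,
    run_interpolation,
    run_smacof,
    select_anchors,
    split_sample,
)

CONVERGENT = InterpolationParams(max_iterations=10_000, tolerance=1e-14)


class TestAnchorDistances:
    def test_zero_distance_to_identical_anchor(self, families_small, aln_params):
        anchors = families_small[:10]
        query = SequenceRecord("q", anchors[3].residues)
        d = anchor_distances(query, anchors, aln_params)
        assert d[3] == 0.0

    def test_ledger_counts_m_per_query(self, families_small, aln_params):
        ledger = CostLedger()
        anchor_distances(families_small[0], families_small[10:20], aln_params, ledger)
        assert ledger.nw_alignments == 10
        anchor_distances(families_small[1], families_small[10:20], aln_params, ledger)
        assert ledger.nw_alignments == 20


class TestSelectAnchors:
    def test_smallest_two(self):
        assert set(select_anchors(np.array([0.5, 0.1, 0.3]), 2)) == {1, 2}

    def test_k_equals_m_returns_all(self):
        assert set(select_anchors(np.array([0.5, 0.1, 0.3]), 3)) == {0, 1, 2}

    def test_k_exceeding_m_rejected(self):
        with pytest.raises(ValidationError):
            select_anchors(np.array([0.5, 0.1]), 3)

    def test_ties_broken_by_lower_index(self):
        sel = select_anchors(np.array([0.2, 0.1, 0.2, 0.1]), 3)
        assert sel.tolist() == [1, 3, 0]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(17)
        d = rng.random(100)
        oracle = sorted(range(100), key=lambda i: (d[i], i))[:7]
        assert select_anchors(d, 7).tolist() == oracle


class TestInterpolatePoint:
    def test_duplicate_shortcut_returns_anchor_exactly(self):
        p = np.array([[1.0, 2.0, 3.0]])
        pt = interpolate_point(np.array([0.0]), p)
        assert np.array_equal(pt.coords, p[0])
        assert pt.n_iterations == 0

    def test_symmetric_two_anchor_closed_form(self):
        anchors = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        pt = interpolate_point(np.array([0.5, 0.5]), anchors, CONVERGENT)
        assert pt.point_stress < 1e-8
        assert pt.coords[0] == pytest.approx(0.5, abs=1e-6)
        d = np.linalg.norm(pt.coords - anchors, axis=1)
        assert np.allclose(d, 0.5, atol=1e-6)

    def test_recovers_embeddable_out_of_sample_point(self, geom50):
        split = split_sample(50, 35, seed=0)
        D = np.asarray(geom50.delta.values, dtype=np.float64)
        anchors = geom50.true_coords[split.in_sample]
        for q in split.out_of_sample[:8]:
            deltas = D[q, split.in_sample]
            sel = select_anchors(deltas, 10)
            pt = interpolate_point(deltas[sel], anchors[sel], CONVERGENT)
            assert np.linalg.norm(pt.coords - geom50.true_coords[q]) < 1e-3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_point_stress_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        anchors = rng.normal(size=(10, 3))
        deltas = np.abs(rng.normal(size=10)) + 0.1
        pt = interpolate_point(deltas, anchors)
        assert np.all(np.diff(pt.stress_trace) <= 1e-12)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValidationError):
            interpolate_point(np.array([np.nan]), np.zeros((1, 3)))


def _make_embedding(records, rng):
    return EmbeddingConfiguration(
        ids=[r.id for r in records], coords=rng.normal(size=(len(records), 3))
    )


class TestRunInterpolation:
    def test_no_out_records_is_identity(self, families_small):
        rng = np.random.default_rng(0)
        emb = _make_embedding(families_small[:10], rng)
        combined, points = run_interpolation(emb, families_small[:10], [])
        assert points == []
        assert np.array_equal(combined.coords, emb.coords)
        assert combined.ids == emb.ids

    def test_duplicate_out_record_lands_on_its_twin(self, families_small, aln_params):
        rng = np.random.default_rng(1)
        in_records = families_small[:10]
        emb = _make_embedding(in_records, rng)
        twin = SequenceRecord("twin", in_records[4].residues)
        combined, _ = run_interpolation(
            emb, in_records, [twin], aln_params, InterpolationParams(k_neighbors=5)
        )
        assert np.array_equal(combined.coords[-1], emb.coords[4])

    def test_in_sample_coordinates_never_move(self, families_small, aln_params):
        rng = np.random.default_rng(2)
        in_records = families_small[:10]
        out_records = families_small[10:20]
        emb = _make_embedding(in_records, rng)
        before = emb.coords.copy()
        combined, _ = run_interpolation(
            emb, in_records, out_records, aln_params, InterpolationParams(k_neighbors=5)
        )
        assert np.array_equal(combined.coords[:10], before)

    def test_processing_order_independent(self, families_small, aln_params):
        rng = np.random.default_rng(3)
        in_records = families_small[:10]
        out_records = families_small[10:20]
        emb = _make_embedding(in_records, rng)
        params = InterpolationParams(k_neighbors=5)
        fwd, _ = run_interpolation(emb, in_records, out_records, aln_params, params)
        rev, _ = run_interpolation(emb, in_records, out_records[::-1], aln_params, params)
        by_id_fwd = dict(zip(fwd.ids, map(tuple, fwd.coords)))
        by_id_rev = dict(zip(rev.ids, map(tuple, rev.coords)))
        assert by_id_fwd == by_id_rev

    def test_worker_count_independent(self, families_small, aln_params):
        rng = np.random.default_rng(4)
        in_records = families_small[:10]
        out_records = families_small[10:25]
        emb = _make_embedding(in_records, rng)
        params = InterpolationParams(k_neighbors=5)
        one, _ = run_interpolation(emb, in_records, out_records, aln_params, params, n_workers=1)
        four, _ = run_interpolation(emb, in_records, out_records, aln_params, params, n_workers=4)
        assert np.array_equal(one.coords, four.coords)

    def test_alignment_cost_contract(self, families_small, aln_params):
        rng = np.random.default_rng(5)
        in_records = families_small[:10]
        out_records = families_small[10:30]
        emb = _make_embedding(in_records, rng)
        ledger = CostLedger()
        run_interpolation(
            emb, in_records, out_records, aln_params,
            InterpolationParams(k_neighbors=5), ledger,
        )
        assert ledger.nw_alignments == 10 * 20  # (N - M) * M
        assert ledger.majorization_iterations > 0

    def test_id_collision_rejected(self, families_small):
        rng = np.random.default_rng(6)
        in_records = families_small[:10]
        emb = _make_embedding(in_records, rng)
        with pytest.raises(ValidationError):
            run_interpolation(emb, in_records, [in_records[0]])

    def test_k_exceeding_in_sample_size_rejected(self, families_small):
        rng = np.random.default_rng(7)
        in_records = families_small[:5]
        emb = _make_embedding(in_records, rng)
        with pytest.raises(ValidationError):
            run_interpolation(
                emb, in_records, families_small[10:12],
                interp_params=InterpolationParams(k_neighbors=10),
            )


def _interpolated_errors(fixture, m, k=10):
    """Mini interpolative run on a geometric fixture; per-point positional
    error of interpolated points after similarity alignment to the truth."""
    n = fixture.delta.n
    from seqmds import DistanceMatrix

    split = split_sample(n, m, seed=0)
    din = DistanceMatrix(
        ids=[fixture.delta.ids[i] for i in split.in_sample],
        values=fixture.delta.values[np.ix_(split.in_sample, split.in_sample)],
    )
    emb = run_smacof(din).embedding
    D = np.asarray(fixture.delta.values, dtype=np.float64)
    coords = np.empty_like(fixture.true_coords)
    coords[split.in_sample] = emb.coords
    for q in split.out_of_sample:
        deltas = D[q, split.in_sample]
        sel = select_anchors(deltas, min(k, m))
        pt = interpolate_point(deltas[sel], emb.coords[sel], CONVERGENT)
        coords[q] = pt.coords
    xc = fixture.true_coords - fixture.true_coords.mean(0)
    yc = coords - coords.mean(0)
    u, s, vt = np.linalg.svd(yc.T @ xc)
    scale = s.sum() / (yc**2).sum()
    resid = xc - scale * (yc @ (u @ vt))
    return np.linalg.norm(resid[split.out_of_sample], axis=1)


class TestDegradation:
    def test_larger_in_sample_no_worse_than_smaller(self):
        from seqmds import generate_geometric

        fixture = generate_geometric(200, 4, seed=13)
        err_half = _interpolated_errors(fixture, 100).mean()
        err_tenth = _interpolated_errors(fixture, 20).mean()
        assert err_half <= err_tenth

    @pytest.mark.parametrize("k", [1, 5, 10, 35])
    def test_anchor_count_sweep_stays_finite(self, geom50, k):
        errs = _interpolated_errors(geom50, 35, k=k)
        assert np.all(np.isfinite(errs))
        if k >= 5:  # with enough anchors the placement is geometrically tight
            assert errs.mean() < 0.05
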