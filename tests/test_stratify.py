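import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tractstrata.datamodel import ConnectomeTriplet, ValidationError
from tractstrata.stratify import (
    ABSENT,
    LONG,
    MIDDLE,
    SHORT,
    LengthBoundaries,
    classify_edges,
    compute_boundaries,
    hc_average_length,
    summarize,
    summarize_weighted,
)

from _oracles import stratified_summary_oracle
from conftest import make_triplet


def triplet_from_edges(edges, n=4, subject_id="t"):
    """Build a triplet from {(i, j): (length, fn, fa)}."""
    L, F, A = np.zeros((n, n)), np.zeros((n, n)), np.zeros((n, n))
    for (i, j), (l, f, a) in edges.items():
        L[i, j] = L[j, i] = l
        F[i, j] = F[j, i] = f
        A[i, j] = A[j, i] = a
    labels = tuple(f"r{i}" for i in range(n))
    return ConnectomeTriplet(subject_id, labels, L, F, A).validate()


class TestHcAverage:
    def test_presence_conditional_mean(self):
        t1 = triplet_from_edges({(0, 1): (10, 2, 0.5), (1, 2): (30, 1, 0.4)})
        t2 = triplet_from_edges({(0, 1): (20, 3, 0.5)})
        avg = hc_average_length([t1, t2])
        assert avg[0, 1] == 15.0          # mean over both carriers
        assert avg[1, 2] == 30.0          # single-carrier edge keeps its value
        assert avg[0, 3] == 0.0           # absent everywhere stays absent
        np.testing.assert_array_equal(avg, avg.T)

    def test_node_order_mismatch_rejected(self):
        t1 = make_triplet("a", n=5)
        t2 = make_triplet("b", n=5)
        t2.node_labels = tuple(reversed(t2.node_labels))
        with pytest.raises(ValidationError, match="node order"):
            hc_average_length([t1, t2])

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            hc_average_length([])


class TestBoundaries:
    def test_equal_width_thirds_of_10_90(self):
        avg = np.zeros((3, 3))
        avg[0, 1] = avg[1, 0] = 10.0
        avg[1, 2] = avg[2, 1] = 90.0
        b = compute_boundaries(avg)
        assert b.l_min == 10.0 and b.l_max == 90.0
        assert b.b1 == pytest.approx(110 / 3)   # 36.666...
        assert b.b2 == pytest.approx(190 / 3)   # 63.333...

    def test_degenerate_range_rejected(self):
        avg = np.zeros((3, 3))
        avg[0, 1] = avg[1, 0] = avg[1, 2] = avg[2, 1] = 42.0
        with pytest.raises(ValidationError, match="degenerate"):
            compute_boundaries(avg)

    def test_no_positive_entries_rejected(self):
        with pytest.raises(ValidationError):
            compute_boundaries(np.zeros((4, 4)))

    def test_matches_independent_scan_on_synthetic_hc(self, small_cohort):
        hc = [t for t in small_cohort.triplets if t.subject_id.startswith("hc")]
        avg = hc_average_length(hc)
        b = compute_boundaries(avg)
        # independent recomputation: brute scan over positive entries
        vals = [avg[i, j] for i in range(avg.shape[0]) for j in range(avg.shape[1])
                if avg[i, j] > 0]
        assert b.l_min == min(vals) and b.l_max == max(vals)
        assert b.b1 == pytest.approx(min(vals) + (max(vals) - min(vals)) / 3, rel=1e-12)

    def test_invalid_orderings_rejected(self):
        with pytest.raises(ValidationError):
            LengthBoundaries(10, 5, 20, 30)
        with pytest.raises(ValidationError):
            LengthBoundaries(0, 10, 25, 30)  # unequal widths


class TestClassify:
    BOUNDS = LengthBoundaries(0.0, 10.0, 20.0, 30.0)

    def _one_edge(self, length):
        return triplet_from_edges({(0, 1): (length, 5, 0.5)})

    @pytest.mark.parametrize(
        "length,expected",
        [
            (5.0, SHORT),
            (10.0, MIDDLE),   # L == b1: half-open convention puts it in middle
            (19.999, MIDDLE),
            (20.0, LONG),     # L == b2 belongs to the top class
            (30.0, LONG),     # top class closed at l_max
            (0.5, SHORT),     # below l_min clamps to short
            (45.0, LONG),     # above l_max clamps to long
        ],
    )
    def test_interval_convention_and_clamping(self, length, expected):
        mask = classify_edges(self._one_edge(length), self.BOUNDS)
        assert mask.labels[0, 1] == expected

    def test_fn_zero_edge_is_absent_whatever_its_length(self):
        trip = triplet_from_edges({(0, 1): (15.0, 3, 0.5)})
        mask = classify_edges(trip, self.BOUNDS)
        assert mask.labels[0, 2] == ABSENT
        assert mask.labels[2, 3] == ABSENT

    def test_hc_average_basis_shares_one_mask_across_subjects(self, small_cohort):
        hc = [t for t in small_cohort.triplets if t.subject_id.startswith("hc")]
        avg = hc_average_length(hc)
        b = compute_boundaries(avg)
        masks = [
            classify_edges(t, b, basis="hc_average", hc_avg_length=avg).labels
            for t in small_cohort.triplets[:5]
        ]
        for m in masks[1:]:
            np.testing.assert_array_equal(masks[0], m)

    def test_hc_average_basis_requires_avg_matrix(self):
        with pytest.raises(ValidationError):
            classify_edges(self._one_edge(5.0), self.BOUNDS, basis="hc_average")


class TestSummarize:
    BOUNDS = LengthBoundaries(0.0, 10.0, 20.0, 30.0)

    def test_fn_sum_and_fa_mean(self):
        trip = triplet_from_edges({
            (0, 1): (5.0, 3, 0.4),
            (0, 2): (7.0, 4, 0.6),
            (1, 2): (15.0, 2, 0.5),
        })
        s = summarize(trip, classify_edges(trip, self.BOUNDS))
        assert s.fn_short == 7.0
        assert s.fa_short == pytest.approx(0.5)
        assert s.fn_middle == 2.0 and s.fn_long == 0.0
        assert s.fa_long is None
        assert s.fn_total == s.fn_short + s.fn_middle + s.fn_long

    def test_matches_per_edge_loop_oracle(self):
        trip = make_triplet(n=12, rng=np.random.default_rng(42))
        b = LengthBoundaries(5.0, 43.0, 81.0, 119.0)
        mask = classify_edges(trip, b)
        s = summarize(trip, mask)
        ref = stratified_summary_oracle(trip, mask.labels)
        assert s.fn_short == ref["fn_short"]
        assert s.fn_middle == ref["fn_middle"]
        assert s.fn_long == ref["fn_long"]
        assert s.fn_total == ref["fn_total"]
        for name in ("short", "middle", "long"):
            got, want = getattr(s, f"fa_{name}"), ref[f"fa_{name}"]
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_fn_weighted_fa_variant(self):
        trip = triplet_from_edges({(0, 1): (5.0, 1, 0.4), (0, 2): (7.0, 3, 0.8)})
        s = summarize_weighted(trip, classify_edges(trip, self.BOUNDS))
        assert s.fa_short == pytest.approx((1 * 0.4 + 3 * 0.8) / 4)


class TestInvariants:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), scale_exp=st.integers(-3, 3))
    def test_partition_conservation_and_scale_equivariance(self, seed, scale_exp):
        rng = np.random.default_rng(seed)
        trip = make_triplet(n=8, rng=rng)
        pos = trip.length[trip.length > 0]
        if pos.size < 2 or pos.min() == pos.max():
            return
        avg = trip.length  # single-subject "HC average"
        b = compute_boundaries(avg)
        mask = classify_edges(trip, b)
        s = summarize(trip, mask)
        # conservation is exact, not approximate
        assert s.fn_short + s.fn_middle + s.fn_long == s.fn_total
        # partition: every existing edge gets exactly one label
        iu = np.triu_indices(8, 1)
        existing = trip.fn[iu] > 0
        labeled = mask.labels[iu] != ABSENT
        assert (existing == labeled).all()
        assert sum(mask.counts().values()) == existing.sum()
        # scale equivariance with an exact power-of-two factor
        k = 2.0 ** scale_exp
        trip2 = ConnectomeTriplet(
            trip.subject_id, trip.node_labels, trip.length * k, trip.fn, trip.fa
        )
        b2 = compute_boundaries(avg * k)
        mask2 = classify_edges(trip2, b2)
        np.testing.assert_array_equal(mask.labels, mask2.labels)

    def test_monotone_boundary_response(self):
        trip = make_triplet(n=10, rng=np.random.default_rng(7))
        b = compute_boundaries(trip.length)
        lab = classify_edges(trip, b).labels
        # raise b1 by moving l_min up: the short set can only grow
        width = (b.l_max - b.l_min) / 3
        for bump in (0.1, 0.5, 1.0):
            b_hi = LengthBoundaries(
                b.l_min, b.l_min + width + bump, b.l_min + 2 * (width + bump),
                b.l_min + 3 * (width + bump),
            )
            lab_hi = classify_edges(trip, b_hi).labels
            was_short = lab == SHORT
            assert (lab_hi[was_short] == SHORT).all()
            was_long_hi = lab_hi == LONG
            assert (lab[was_long_hi] == LONG).all()
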