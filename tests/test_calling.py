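"""Clustering, orientation, novelty and event arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from temates.calling import (
    Cluster,
    call_event,
    classify_novelty,
    classify_orientation,
    cluster_anchors,
    format_event_type,
    orientation_vote,
    source_element,
)
from temates.evidence import CallingParams

from conftest import make_evidence, make_record


def brute_force_clusters(positions, window):
    """Independent single-linkage oracle via graph connected components."""
    pos = np.asarray(positions)
    n = len(pos)
    if n == 0:
        return []
    adj = (np.abs(pos[:, None] - pos[None, :]) <= window).astype(int)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    return sorted(sorted(g) for g in groups.values())


class TestClustering:
    def test_single_anchor_single_cluster(self, default_params):
        clusters = cluster_anchors([make_evidence(100)], default_params)
        assert len(clusters) == 1 and len(clusters[0]) == 1

    def test_gap_splits_clusters(self):
        params = CallingParams(insert_mean=150, insert_sd=50, window_multiplier=3)
        assert params.window == 300
        evidence = [make_evidence(p) for p in (100, 150, 900)]
        clusters = cluster_anchors(evidence, params)
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 2]
        positions = sorted(tuple(e.anchor_pos for e in c.evidence) for c in clusters)
        assert positions == [(100, 150), (900,)]

    def test_items_never_share_a_cluster(self, default_params):
        gypsy = make_record("AT1TE002", superfamily="Gypsy", family="ATGP1")
        evidence = [
            make_evidence(1000, item="Copia"),
            make_evidence(1001, item="Gypsy", record=gypsy),
        ]
        clusters = cluster_anchors(evidence, default_params)
        assert len(clusters) == 2
        assert all(len({e.item for e in c.evidence}) == 1 for c in clusters)

    def test_individuals_are_pooled(self, default_params):
        evidence = [
            make_evidence(1000, individual="a"),
            make_evidence(1050, individual="b"),
        ]
        clusters = cluster_anchors(evidence, default_params)
        assert len(clusters) == 1
        assert clusters[0].support_by_individual() == {"a": 1, "b": 1}

    @given(
        positions=st.lists(st.integers(0, 5000), min_size=0, max_size=60),
        window=st.integers(1, 800),
    )
    def test_sweep_equals_bruteforce_single_linkage(self, positions, window):
        # halves are exact in binary, so params.window == window exactly
        params = CallingParams(
            insert_mean=window / 2, insert_sd=window / 2, window_multiplier=1
        )
        assert params.window == window
        evidence = [make_evidence(p, name=f"r{i}") for i, p in enumerate(positions)]
        clusters = cluster_anchors(evidence, params)
        got = sorted(sorted(e.anchor_pos for e in c.evidence) for c in clusters)
        expected = [
            sorted(positions[i] for i in grp)
            for grp in brute_force_clusters(positions, window)
        ]
        assert got == sorted(expected)


class TestOrientation:
    """Votes derive from inner-facing mate geometry against the source strand."""

    def test_parallel_insertion_plus_source(self):
        # source copy on '+': anchor '+' with mate '-' is the parallel layout
        ev = make_evidence(100, anchor_strand="+", mate_strand="-")
        assert orientation_vote(ev) == "parallel"
        ev = make_evidence(100, anchor_strand="-", mate_strand="+")
        assert orientation_vote(ev) == "parallel"

    def test_inverse_insertion_plus_source(self):
        ev = make_evidence(100, anchor_strand="+", mate_strand="+")
        assert orientation_vote(ev) == "inverse"

    def test_minus_source_flips_the_vote(self):
        minus = make_record(strand="-")
        ev = make_evidence(100, record=minus, anchor_strand="+", mate_strand="-")
        assert orientation_vote(ev) == "inverse"

    def test_unknown_source_strand_gives_no_vote(self):
        unknown = make_record(strand=".")
        ev = make_evidence(100, record=unknown)
        assert orientation_vote(ev) is None

    def test_majority_vote_counts(self):
        cluster = Cluster(
            "chr1",
            "Copia",
            [make_evidence(100 + i, mate_strand="-", name=f"p{i}") for i in range(10)]
            + [make_evidence(200, mate_strand="+", name="i0")],
        )
        assert classify_orientation(cluster) == ("parallel", 10, 1)

    def test_tie_is_uncertain(self):
        cluster = Cluster(
            "chr1",
            "Copia",
            [make_evidence(100 + i, mate_strand="-", name=f"p{i}") for i in range(5)]
            + [make_evidence(200 + i, mate_strand="+", name=f"i{i}") for i in range(5)],
        )
        assert classify_orientation(cluster) == ("uncertain", 5, 5)

    def test_any_unknown_strand_pair_forces_uncertain(self):
        unknown = make_record(strand=".")
        cluster = Cluster(
            "chr1",
            "Copia",
            [make_evidence(100, mate_strand="-"), make_evidence(101, record=unknown)],
        )
        orientation, _, _ = classify_orientation(cluster)
        assert orientation == "uncertain"


class TestNovelty:
    def test_event_at_same_item_locus_is_old(self, small_index, default_params):
        # Copia annotated on chr1 at 1000-2000 (1-based)
        assert (
            classify_novelty("chr1", 1500, "Copia", small_index, default_params)
            == "old"
        )

    def test_nearby_within_window_is_old(self, small_index, default_params):
        assert (
            classify_novelty("chr1", 2500, "Copia", small_index, default_params)
            == "old"
        )

    def test_far_event_is_new(self, small_index, default_params):
        assert (
            classify_novelty("chr1", 90_000, "Copia", small_index, default_params)
            == "new"
        )

    def test_other_item_locus_does_not_make_old(self, small_index, default_params):
        # position inside the MuDR copy only: a Copia call there is new
        assert (
            classify_novelty("chr1", 51_000, "Copia", small_index, default_params)
            == "new"
        )


class TestEventArithmetic:
    """Support totals and orientation labels on engineered clusters."""

    def make_cluster(self, n_parallel, n_inverse, record, item, pos=84_000):
        evidence = [
            make_evidence(pos + i, item=item, record=record, mate_strand="-",
                          name=f"p{i}")
            for i in range(n_parallel)
        ] + [
            make_evidence(pos + 50 + i, item=item, record=record, mate_strand="+",
                          name=f"i{i}")
            for i in range(n_inverse)
        ]
        return Cluster("chr1", item, evidence)

    @pytest.mark.parametrize(
        "n_parallel, n_inverse, expected_orientation, superfamily, te_class",
        [
            (4, 11, "inverse", "MuDR", "DNA"),
            (47, 10, "parallel", "Copia", "LTR"),
            (10, 1, "parallel", "Helitron", "RC"),
        ],
    )
    def test_support_and_majority_orientation(
        self, small_index, default_params,
        n_parallel, n_inverse, expected_orientation, superfamily, te_class,
    ):
        record = make_record(
            "AT9TE100", superfamily=superfamily, te_class=te_class, strand="+"
        )
        cluster = self.make_cluster(n_parallel, n_inverse, record, superfamily)
        event = call_event(cluster, small_index, default_params)
        assert event is not None
        assert event.read_pair_support == n_parallel + n_inverse
        assert event.orientation == expected_orientation
        assert (event.p_pairs, event.i_pairs) == (n_parallel, n_inverse)
        assert event.p_pairs + event.i_pairs == event.read_pair_support
        assert event.novelty == "new"

    def test_old_event_reported_uncertain_with_suppressed_counts(
        self, small_index, default_params, copia_record
    ):
        cluster = self.make_cluster(9, 1, copia_record, "Copia", pos=1400)
        event = call_event(cluster, small_index, default_params)
        assert event.novelty == "old"
        assert event.orientation == "uncertain"
        assert event.p_pairs is None and event.i_pairs is None

    def test_below_min_support_yields_nothing(self, small_index):
        params = CallingParams(min_support=3)
        cluster = Cluster("chr1", "Copia", [make_evidence(80_000)])
        assert call_event(cluster, small_index, params) is None

    def test_loc_is_floored_median(self, small_index, default_params):
        cluster = Cluster(
            "chr1",
            "Copia",
            [make_evidence(p, name=f"r{p}") for p in (80_000, 80_101, 80_500, 80_999)],
        )
        event = call_event(cluster, small_index, default_params)
        assert event.loc == (80_101 + 80_500) // 2

    def test_length_comes_from_most_supported_source(self, small_index, default_params):
        a = make_record("AT9TE001", start=0, end=1000, strand="+")
        b = make_record("AT9TE002", start=0, end=2000, strand="+")
        evidence = (
            [make_evidence(80_000 + i, record=a, name=f"a{i}") for i in range(3)]
            + [make_evidence(80_100 + i, record=b, name=f"b{i}") for i in range(2)]
        )
        event = call_event(Cluster("chr1", "Copia", evidence), small_index, default_params)
        assert event.length == 1000

    def test_source_tie_breaks_to_smallest_te_id(self):
        a = make_record("AT9TE002", start=0, end=1000, strand="+")
        b = make_record("AT9TE001", start=0, end=2000, strand="+")
        evidence = [
            make_evidence(80_000, record=a, name="a"),
            make_evidence(80_001, record=b, name="b"),
        ]
        assert source_element(Cluster("chr1", "Copia", evidence)).te_id == "AT9TE001"

    def test_calling_is_deterministic_under_input_order(self, small_index, default_params):
        evidence = [
            make_evidence(80_000 + 37 * i, name=f"r{i}", mate_strand="-" if i % 3 else "+")
            for i in range(12)
        ]
        events_fwd = [
            call_event(c, small_index, default_params)
            for c in cluster_anchors(evidence, default_params)
        ]
        events_rev = [
            call_event(c, small_index, default_params)
            for c in cluster_anchors(evidence[::-1], default_params)
        ]
        assert events_fwd == events_rev


@pytest.mark.parametrize(
    "te_class, superfamily, expected",
    [
        ("LTR", "Copia", "TE+LTR/Copia/LTR/Copia"),
        ("RC", "Helitron", "TE+RC/Helitron/RC/Helitron"),
        ("DNA", "HAT", "TE+DNA/HAT/DNA/HAT"),
        ("DNA", "MuDR", "TE+DNA/MuDR/DNA/MuDR"),
        ("LINE", "L1", "TE+LINE/L1/LINE/L1"),
    ],
)
def test_format_event_type(te_class, superfamily, expected):
    record = make_record(te_class=te_class, superfamily=superfamily)
    assert format_event_type(record) == expected
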