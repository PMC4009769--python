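"""Virtual reference construction, insertion planting, and read simulation."""

import numpy as np
import pytest

from temates.annotation import AnnotationIndex
from temates.simulate import (
    SimParams,
    SimulationError,
    build_virtual_reference,
    mutate_snps,
    n_pairs_for,
    plant_insertions,
    revcomp,
    simulate_read_pairs,
)

from conftest import make_record


@pytest.fixture
def genome(rng):
    return {
        "chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)]),
        "chr2": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 6_000)]),
    }


@pytest.fixture
def index():
    return AnnotationIndex(
        [
            make_record("TE1", "chr1", 1000, 2000, strand="+"),
            make_record("TE2", "chr1", 5000, 5600, superfamily="Gypsy",
                        family="ATGP1", strand="-"),
            make_record("TE3", "chr2", 2000, 2900, superfamily="MuDR",
                        te_class="DNA", family="ATMU1", strand="+"),
        ]
    )


class TestVirtualReference:
    def test_no_annotation_means_identity(self, genome):
        virtual = build_virtual_reference(genome, AnnotationIndex([]))
        assert virtual.te_free == genome
        assert virtual.contigs == {}

    def test_excision_lengths(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        assert len(virtual.te_free["chr1"]) == 10_000 - 1000 - 600
        assert len(virtual.contigs["TE1"]) == 1000
        assert virtual.contigs["TE1"] == genome["chr1"][1000:2000]

    def test_total_base_count_conserved(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        assert virtual.total_length == sum(map(len, genome.values()))

    def test_excision_points_shift_left(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        assert virtual.excision_points["TE1"] == ("chr1", 1000)
        # TE2 started at 5000 but 1000 TE bases were removed before it
        assert virtual.excision_points["TE2"] == ("chr1", 4000)

    def test_overlapping_records_are_merged_into_one_excision(self, genome):
        overlapping = AnnotationIndex(
            [
                make_record("TEa", "chr1", 1000, 2000, strand="+"),
                make_record("TEb", "chr1", 1500, 2500, strand="+"),
            ]
        )
        virtual = build_virtual_reference(genome, overlapping)
        assert len(virtual.te_free["chr1"]) == 10_000 - 1500
        assert virtual.contigs["TEa"] == genome["chr1"][1000:2000]
        assert virtual.contigs["TEb"] == genome["chr1"][1500:2500]
        assert virtual.excision_points["TEa"] == virtual.excision_points["TEb"]


class TestPlanting:
    def test_zero_insertions(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        sample = plant_insertions(virtual, 0, seed=1)
        assert sample.sequences == virtual.te_free
        assert sample.truth == []

    def test_length_conservation(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        sample = plant_insertions(virtual, 3, seed=1)
        planted = sum(len(virtual.contigs[t.te_id]) for t in sample.truth)
        assert sample.total_length == sum(map(len, virtual.te_free.values())) + planted

    def test_determinism(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        a = plant_insertions(virtual, 3, seed=9)
        b = plant_insertions(virtual, 3, seed=9)
        assert a.truth == b.truth
        assert a.sequences == b.sequences

    def test_planted_sequence_matches_contig(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        sample = plant_insertions(virtual, 3, seed=2)
        for chrom, blocks in sample.blocks.items():
            for b in blocks:
                if not b.is_te:
                    continue
                got = sample.sequences[chrom][b.sample_start : b.sample_start + b.length]
                body = virtual.contigs[b.target]
                assert got == (body if b.strand == "+" else revcomp(body))

    def test_too_many_insertions_rejected(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        with pytest.raises(SimulationError):
            plant_insertions(virtual, 4, seed=1)


class TestSnps:
    def test_zero_snps_identity(self, genome):
        assert mutate_snps(genome, 0, seed=1) == genome

    def test_hamming_distance_equals_n_snps(self, genome):
        mutated = mutate_snps(genome, 250, seed=1)
        diff = sum(
            a != b
            for chrom in genome
            for a, b in zip(genome[chrom], mutated[chrom])
        )
        assert diff == 250

    def test_determinism(self, genome):
        assert mutate_snps(genome, 100, seed=3) == mutate_snps(genome, 100, seed=3)


class TestReads:
    def test_pair_count_formula(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        sample = plant_insertions(virtual, 0, seed=1)
        params = SimParams(coverage=2, read_length=50, insert_mean=200, insert_sd=30)
        pairs = simulate_read_pairs(sample, params)
        assert len(pairs) == n_pairs_for(params, sample.total_length)
        assert n_pairs_for(params, 10_000) == 200

    def test_error_free_reads_are_exact_substrings(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        sample = plant_insertions(virtual, 2, seed=5)
        params = SimParams(coverage=1, read_length=60, insert_mean=250, insert_sd=40)
        joined = {c: s for c, s in sample.sequences.items()}
        for r1, r2 in simulate_read_pairs(sample, params):
            for read in (r1, r2):
                found = any(
                    read.seq in s or revcomp(read.seq) in s for s in joined.values()
                )
                assert found

    def test_reads_in_te_bodies_get_mapq_zero(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        sample = plant_insertions(virtual, 3, seed=5)
        params = SimParams(coverage=5, read_length=60, insert_mean=250, insert_sd=40)
        te_names = set(virtual.contigs)
        for r1, r2 in simulate_read_pairs(sample, params):
            for read in (r1, r2):
                if read.ref_name in te_names:
                    assert read.mapq == 0
                else:
                    assert read.mapq == 60

    def test_empirical_depth_tracks_requested_coverage(self, rng):
        genome = {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120_000)])}
        virtual = build_virtual_reference(genome, AnnotationIndex([]))
        sample = plant_insertions(virtual, 0, seed=1)
        params = SimParams(coverage=8, read_length=100, insert_mean=300, insert_sd=50)
        pairs = simulate_read_pairs(sample, params)
        bases = sum(len(r.seq) for pair in pairs for r in pair)
        depth = bases / 120_000
        assert depth == pytest.approx(8, rel=0.10)

    def test_determinism_under_fixed_seed(self, genome, index):
        virtual = build_virtual_reference(genome, index)
        sample = plant_insertions(virtual, 2, seed=5)
        params = SimParams(coverage=2, read_length=50, seed=77)
        a = simulate_read_pairs(sample, params)
        b = simulate_read_pairs(sample, params)
        assert a == b

    def test_insert_must_exceed_read_length(self):
        with pytest.raises(SimulationError):
            SimParams(read_length=150, insert_mean=100)
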