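import numpy as np
import pysam
import pytest
from hypothesis import settings

from temates.annotation import AnnotationIndex, TERecord
from temates.evidence import AnchorEvidence, CallingParams

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


def make_record(
    te_id="AT1TE001",
    chrom="chr1",
    start=999,
    end=2000,
    family="ATCOPIA4",
    superfamily="Copia",
    te_class="LTR",
    strand="+",
):
    return TERecord(
        chrom=chrom,
        start=start,
        end=end,
        te_id=te_id,
        family=family,
        superfamily=superfamily,
        te_class=te_class,
        strand=strand,
    )


def make_evidence(
    pos,
    item="Copia",
    record=None,
    individual="ind1",
    chrom="chr1",
    anchor_strand="+",
    mate_strand="-",
    mapq=60,
    name=None,
):
    record = record or make_record()
    return AnchorEvidence(
        individual_id=individual,
        anchor_chrom=chrom,
        anchor_pos=pos,
        anchor_strand=anchor_strand,
        anchor_mapq=mapq,
        te_record=record,
        te_mate_strand=mate_strand,
        item=item,
        read_name=name or f"r{pos}_{individual}_{anchor_strand}{mate_strand}",
    )


@pytest.fixture
def copia_record():
    return make_record()


@pytest.fixture
def small_index():
    """Two chromosomes, four superfamilies, one overlapping pair."""
    records = [
        make_record("AT1TE001", "chr1", 999, 2000, "ATCOPIA4", "Copia", "LTR", "+"),
        make_record("AT1TE002", "chr1", 1800, 2600, "ATGP1", "Gypsy", "LTR", "-"),
        make_record("AT1TE003", "chr1", 50_000, 53_000, "ATMU3", "MuDR", "DNA", "+"),
        make_record("AT2TE001", "chr2", 5_000, 9_000, "ATREP2", "Helitron", "RC", "."),
        make_record("AT2TE002", "chr2", 30_000, 30_900, "ATCOPIA4", "Copia", "LTR", "-"),
    ]
    return AnnotationIndex(records, chrom_lengths={"chr1": 100_000, "chr2": 60_000})


def write_sam(path, reads, refs):
    """Write paired SAM records; each read is a dict of pysam attributes."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in refs.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["name"]
            seq = r.get("seq", "A" * r.get("length", 50))
            a.query_sequence = seq
            a.flag = r["flag"]
            a.reference_id = out.header.get_tid(r["ref"])
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = f"{len(seq)}M"
            a.next_reference_id = out.header.get_tid(r["mate_ref"])
            a.next_reference_start = r["mate_pos"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)
    return path


def make_pair(name, anchor_ref, anchor_pos, mate_ref, mate_pos, length=50,
              anchor_mapq=60, mate_mapq=0, anchor_reverse=False, mate_reverse=True):
    """Two SAM-record dicts forming one aligned pair."""
    f1 = 0x1 | 0x40 | (0x10 if anchor_reverse else 0) | (0x20 if mate_reverse else 0)
    f2 = 0x1 | 0x80 | (0x10 if mate_reverse else 0) | (0x20 if anchor_reverse else 0)
    return [
        {"name": name, "flag": f1, "ref": anchor_ref, "pos": anchor_pos,
         "mate_ref": mate_ref, "mate_pos": mate_pos, "length": length,
         "mapq": anchor_mapq},
        {"name": name, "flag": f2, "ref": mate_ref, "pos": mate_pos,
         "mate_ref": anchor_ref, "mate_pos": anchor_pos, "length": length,
         "mapq": mate_mapq},
    ]


@pytest.fixture
def default_params():
    return CallingParams()


@pytest.fixture(scope="session")
def mini_fixture_dir(tmp_path_factory):
    from temates.fixtures import make_fixture

    out = tmp_path_factory.mktemp("fixture")
    make_fixture(out, seed=11, scale="mini")
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
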