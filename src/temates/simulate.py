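"""Validation-data simulator: virtual reference, planted TEs, reads.

The simulation mirrors how the calling method is validated end to end
without an external aligner:

1. **Virtual reference** — every annotated TE interval is excised from the
   reference chromosomes; each excised sequence becomes its own contig named
   by te_id. The TE-free chromosomes plus TE contigs are the coordinate
   system the caller sees.
2. **Sample genome** — TE sequences are inserted back into the TE-free
   chromosomes at uniformly random breakpoints (random strand), and a fixed
   number of SNPs is sprinkled over the result. The insertion list is the
   scoring truth.
3. **Read pairs** — inner-facing pairs are drawn from the sample genome with
   Normal(insert_mean, insert_sd) fragment lengths and per-base substitution
   errors. A truth SAM places each read at its true origin projected onto
   the virtual reference: flank-derived reads on TE-free chromosomes with
   MAPQ 60, reads from planted TE bodies on the corresponding TE contig with
   MAPQ 0 (a read inside a TE body would multi-map in practice). Reads
   straddling a breakpoint go to the side holding the majority of their
   bases.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pysam

from .annotation import AnnotationIndex

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Read-simulation settings.

    Defaults match the population-sequencing regime the method targets:
    20x coverage, 100 bp reads, 300 +/- 100 bp inserts.
    """

    coverage: float = 20.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 100.0
    n_snps: int = 0
    base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.coverage, self.read_length, self.insert_mean, self.insert_sd) <= 0:
            raise SimulationError("coverage, read_length and insert stats must be > 0")
        if not 0 <= self.base_error_rate < 1:
            raise SimulationError("base_error_rate must be in [0, 1)")
        if self.insert_mean <= self.read_length:
            raise SimulationError("insert_mean must exceed read_length")


@dataclass(frozen=True)
class TruthInsertion:
    """One planted insertion, on TE-free chromosome coordinates."""

    chrom: str
    pos: int  # 1-based position of the flank base immediately left of the insertion
    te_id: str
    superfamily: str
    strand: str


@dataclass
class VirtualReference:
    """TE-free chromosomes plus one contig per annotated TE copy."""

    te_free: dict[str, str]
    contigs: dict[str, str]
    # te_id -> (chrom, 0-based excision breakpoint on the TE-free chromosome)
    excision_points: dict[str, tuple[str, int]]

    @property
    def total_length(self) -> int:
        return sum(map(len, self.te_free.values())) + sum(
            map(len, self.contigs.values())
        )


@dataclass
class _Block:
    """One mosaic segment of a sample chromosome.

    Maps sample coordinates [sample_start, sample_start+length) onto the
    virtual reference: either a TE-free chromosome slice (strand '+') or a
    planted TE contig (possibly '-').
    """

    sample_start: int
    length: int
    target: str  # chromosome or te_id contig name
    target_start: int
    strand: str
    is_te: bool


@dataclass
class SampleGenome:
    """A simulated individual: sequences plus the truth mosaic map."""

    sequences: dict[str, str]
    truth: list[TruthInsertion]
    blocks: dict[str, list[_Block]] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(map(len, self.sequences.values()))


def build_virtual_reference(
    genome: dict[str, str], index: AnnotationIndex
) -> VirtualReference:
    """Excise every annotated TE into its own contig.

    Overlapping annotations are excised as one merged block, with each
    original record's contig sliced out of the merged region, so the total
    base count is conserved exactly.
    """
    te_free: dict[str, str] = {}
    contigs: dict[str, str] = {}
    excision: dict[str, tuple[str, int]] = {}
    for chrom, seq in genome.items():
        recs = [r for r in index.records if r.chrom == chrom]
        for r in recs:
            if r.end > len(seq):
                raise SimulationError(
                    f"annotation {r.te_id} exceeds {chrom} length {len(seq)}"
                )
        # merge overlapping/adjacent-overlap intervals
        merged: list[list] = []  # [start, end, [records]]
        for r in sorted(recs, key=lambda r: (r.start, r.end)):
            if merged and r.start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], r.end)
                merged[-1][2].append(r)
            else:
                merged.append([r.start, r.end, [r]])
        pieces = []
        cursor = 0
        removed = 0
        for start, end, block_recs in merged:
            pieces.append(seq[cursor:start])
            for r in block_recs:
                contigs[r.te_id] = seq[r.start : r.end]
                excision[r.te_id] = (chrom, start - removed)
            removed += end - start
            cursor = end
        pieces.append(seq[cursor:])
        te_free[chrom] = "".join(pieces)
    # Base count is conserved exactly for non-overlapping annotations; when
    # two records overlap, the shared bases appear in both contigs (each
    # contig is the full original record sliced from the merged excision).
    return VirtualReference(te_free=te_free, contigs=contigs, excision_points=excision)


def plant_insertions(
    virtual: VirtualReference,
    n_or_all: int | str,
    seed: int | np.random.Generator,
    te_ids: list[str] | None = None,
) -> SampleGenome:
    """Insert TE contigs back into the TE-free chromosomes at random spots.

    Sampling of elements is without replacement; breakpoints are uniform
    over the TE-free chromosomes (never inside another planted copy, since
    all breakpoints are chosen on TE-free coordinates first). Returns the
    sample genome with its truth list and mosaic block map.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = sorted(te_ids) if te_ids is not None else sorted(virtual.contigs)
    if n_or_all == "all":
        n = len(pool)
    else:
        n = int(n_or_all)
    if n > len(pool):
        raise SimulationError(
            f"requested {n} insertions but only {len(pool)} TE contigs available"
        )
    chosen = list(rng.choice(pool, size=n, replace=False)) if n else []

    chroms = sorted(virtual.te_free)
    lengths = np.array([len(virtual.te_free[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum() if lengths.sum() else None

    placements: list[tuple[str, int, str, str]] = []  # chrom, pos0, te_id, strand
    used: set[tuple[str, int]] = set()
    for te_id in chosen:
        while True:
            chrom = str(rng.choice(chroms, p=weights))
            pos0 = int(rng.integers(0, len(virtual.te_free[chrom]) + 1))
            if (chrom, pos0) not in used:
                used.add((chrom, pos0))
                break
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((chrom, pos0, te_id, strand))
    placements.sort()

    sequences: dict[str, str] = {}
    blocks: dict[str, list[_Block]] = {}
    truth: list[TruthInsertion] = []
    for chrom in chroms:
        base = virtual.te_free[chrom]
        here = [p for p in placements if p[0] == chrom]
        pieces: list[str] = []
        chrom_blocks: list[_Block] = []
        cursor = 0  # TE-free coordinate
        offset = 0  # sample coordinate of the next piece
        for _, pos0, te_id, strand in here:
            flank = base[cursor:pos0]
            if flank:
                chrom_blocks.append(
                    _Block(offset, len(flank), chrom, cursor, "+", False)
                )
                pieces.append(flank)
                offset += len(flank)
            body = virtual.contigs[te_id]
            planted = body if strand == "+" else revcomp(body)
            chrom_blocks.append(
                _Block(offset, len(planted), te_id, 0, strand, True)
            )
            pieces.append(planted)
            offset += len(planted)
            cursor = pos0
        tail = base[cursor:]
        if tail:
            chrom_blocks.append(_Block(offset, len(tail), chrom, cursor, "+", False))
            pieces.append(tail)
        sequences[chrom] = "".join(pieces)
        blocks[chrom] = chrom_blocks
    for chrom, pos0, te_id, strand in placements:
        truth.append(
            TruthInsertion(
                chrom=chrom,
                pos=pos0,  # 1-based base left of the breakpoint == 0-based breakpoint
                te_id=te_id,
                superfamily="",
                strand=strand,
            )
        )
    return SampleGenome(sequences=sequences, truth=truth, blocks=blocks)


def annotate_truth(sample: SampleGenome, index: AnnotationIndex) -> None:
    """Fill superfamily labels on truth records from the annotation index."""
    sample.truth = [
        TruthInsertion(
            chrom=t.chrom,
            pos=t.pos,
            te_id=t.te_id,
            superfamily=index.item_at_level(t.te_id, "superfamily"),
            strand=t.strand,
        )
        for t in sample.truth
    ]


def mutate_snps(
    genome: dict[str, str], n_snps: int, seed: int | np.random.Generator
) -> dict[str, str]:
    """Mutate exactly n_snps distinct positions, each to a different base."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = [len(genome[c]) for c in chroms]
    total = sum(lengths)
    if n_snps > total:
        raise SimulationError(f"n_snps {n_snps} exceeds genome length {total}")
    if n_snps == 0:
        return dict(genome)
    flat = rng.choice(total, size=n_snps, replace=False)
    flat.sort()
    bounds = np.cumsum([0] + lengths)
    out = {}
    arrays = {c: np.frombuffer(genome[c].encode(), dtype="S1").copy() for c in chroms}
    for pos in flat:
        ci = int(np.searchsorted(bounds, pos, side="right")) - 1
        chrom = chroms[ci]
        local = int(pos - bounds[ci])
        old = arrays[chrom][local].decode().upper()
        choices = [b for b in "ACGT" if b != old]
        arrays[chrom][local] = rng.choice(choices).encode()
    for c in chroms:
        out[c] = arrays[c].tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimRead:
    name: str
    seq: str
    is_read1: bool
    ref_name: str
    pos0: int
    strand: str
    mapq: int


def n_pairs_for(params: SimParams, genome_length: int) -> int:
    return int(round(params.coverage * genome_length / (2 * params.read_length)))


def _project(blocks: list[_Block], start: int, length: int) -> tuple[str, int, bool, bool]:
    """Project a read interval onto the virtual reference.

    Returns (target, target_pos0, flip_strand, is_te) using the block holding
    the majority of the read's bases; the position is clipped into the block.
    """
    starts = [b.sample_start for b in blocks]
    i = max(0, bisect_right(starts, start) - 1)
    best, best_ov = None, -1
    j = i
    end = start + length
    while j < len(blocks) and blocks[j].sample_start < end:
        b = blocks[j]
        ov = min(b.sample_start + b.length, end) - max(b.sample_start, start)
        if ov > best_ov:
            best, best_ov = b, ov
        j += 1
    assert best is not None
    off = min(max(start, best.sample_start), best.sample_start + best.length - 1)
    off -= best.sample_start
    if best.strand == "-":
        # planted reverse copy: read start maps to contig coordinate of its end
        pos = best.length - off - length
        pos = min(max(pos, 0), max(best.length - 1, 0))
        return best.target, best.target_start + pos, True, best.is_te
    return best.target, best.target_start + off, False, best.is_te


def simulate_read_pairs(
    sample: SampleGenome, params: SimParams, rng: np.random.Generator | None = None
) -> list[tuple[SimRead, SimRead]]:
    """Draw inner-facing read pairs from the sample genome.

    The number of pairs is round(coverage * L / (2 * read_length)). Fragment
    lengths are Normal(insert_mean, insert_sd) truncated below at twice the
    read length; per-base substitution errors are applied at
    ``base_error_rate`` after placement, so truth positions are exact.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    rl = params.read_length
    chroms = sorted(sample.sequences)
    lengths = np.array([len(sample.sequences[c]) for c in chroms], dtype=float)
    total = int(lengths.sum())
    n_pairs = n_pairs_for(params, total)
    weights = lengths / lengths.sum()

    pairs: list[tuple[SimRead, SimRead]] = []
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=weights)
    frag_lens = rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)
    for k in range(n_pairs):
        chrom = chroms[int(chrom_idx[k])]
        seq = sample.sequences[chrom]
        L = len(seq)
        frag = max(2 * rl, int(round(frag_lens[k])))
        frag = min(frag, L)
        start = int(rng.integers(0, L - frag + 1))
        end = start + frag

        fwd_seq = seq[start : start + rl]
        rev_seq = revcomp(seq[end - rl : end])
        blocks = sample.blocks.get(chrom) or [_Block(0, L, chrom, 0, "+", False)]
        t1, p1, flip1, te1 = _project(blocks, start, rl)
        t2, p2, flip2, te2 = _project(blocks, end - rl, rl)

        name = f"sim{k}"
        fwd = SimRead(
            name=name,
            seq=_apply_errors(fwd_seq, params.base_error_rate, rng),
            is_read1=True,
            ref_name=t1,
            pos0=p1,
            strand="-" if flip1 else "+",
            mapq=0 if te1 else 60,
        )
        rev = SimRead(
            name=name,
            seq=_apply_errors(rev_seq, params.base_error_rate, rng),
            is_read1=False,
            ref_name=t2,
            pos0=p2,
            strand="+" if flip2 else "-",
            mapq=0 if te2 else 60,
        )
        # which physical end is read 1 is arbitrary in a library
        if rng.random() < 0.5:
            fwd.is_read1, rev.is_read1 = False, True
            pairs.append((rev, fwd))
        else:
            pairs.append((fwd, rev))
    return pairs


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for h in hits:
        choices = [b for b in "ACGT" if b != arr[h]]
        arr[h] = rng.choice(choices)
    return "".join(arr)


def write_truth_sam(
    pairs: list[tuple[SimRead, SimRead]],
    virtual: VirtualReference,
    path,
) -> None:
    """Write truth alignments against the virtual reference as SAM text."""
    names = sorted(virtual.te_free) + sorted(virtual.contigs)
    lengths = {**{c: len(s) for c, s in virtual.te_free.items()},
               **{c: len(s) for c, s in virtual.contigs.items()}}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": lengths[n]} for n in names],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        hdr = out.header
        for r1, r2 in pairs:
            for me, mate in ((r1, r2), (r2, r1)):
                a = pysam.AlignedSegment(hdr)
                a.query_name = me.name
                a.query_sequence = me.seq
                a.flag = (
                    0x1
                    | (0x10 if me.strand == "-" else 0)
                    | (0x20 if mate.strand == "-" else 0)
                    | (0x40 if me.is_read1 else 0x80)
                )
                a.reference_id = hdr.get_tid(me.ref_name)
                a.reference_start = me.pos0
                a.mapping_quality = me.mapq
                a.cigarstring = f"{len(me.seq)}M"
                a.next_reference_id = hdr.get_tid(mate.ref_name)
                a.next_reference_start = mate.pos0
                a.template_length = 0
                a.query_qualities = pysam.qualitystring_to_array("I" * len(me.seq))
                out.write(a)


def write_fastq(pairs: list[tuple[SimRead, SimRead]], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in pairs:
            first, second = (r1, r2) if r1.is_read1 else (r2, r1)
            f1.write(f"@{first.name}/1\n{first.seq}\n+\n{'I' * len(first.seq)}\n")
            f2.write(f"@{second.name}/2\n{second.seq}\n+\n{'I' * len(second.seq)}\n")


def write_truth_tsv(truth: list[TruthInsertion], path, individual: str | None = None) -> None:
    with open(path, "w") as fh:
        cols = ["chrom", "pos", "te_id", "superfamily", "strand"]
        if individual is not None:
            cols = ["individual"] + cols
        fh.write("\t".join(cols) + "\n")
        for t in sorted(truth, key=lambda t: (t.chrom, t.pos, t.te_id)):
            row = [t.chrom, str(t.pos), t.te_id, t.superfamily, t.strand]
            if individual is not None:
                row = [individual] + row
            fh.write("\t".join(row) + "\n")


def read_truth_tsv(path) -> list[TruthInsertion] | dict[str, list[TruthInsertion]]:
    """Read a truth TSV; returns a dict per individual if that column exists."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    def mk(row):
        return TruthInsertion(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            te_id=row["te_id"],
            superfamily=row["superfamily"],
            strand=row["strand"],
        )
    if "individual" in df.columns:
        out: dict[str, list[TruthInsertion]] = {}
        for _, row in df.iterrows():
            out.setdefault(str(row["individual"]), []).append(mk(row))
        return out
    return [mk(row) for _, row in df.iterrows()]
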