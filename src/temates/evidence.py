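"""Collect informative mate-pairs from paired-end alignments.

A read pair is informative for TE calling when exactly one end (the anchor)
maps with good quality to a region outside every annotated TE while its mate
lands inside an annotated TE copy. The anchor localizes the insertion flank
uniquely; the TE-side mate identifies *which* item (at the active hierarchy
level) jumped there, even though its exact placement within the TE copies is
unreliable. Consequently only the anchor carries a mapping-quality
requirement.

Two reference styles are supported:

* ``annotated`` — reads aligned to the ordinary reference; TE membership is
  decided by interval overlap against the annotation index.
* ``virtual`` — reads aligned to a virtual reference in which annotated TEs
  were excised into separate contigs named by te_id; a mate on a TE contig
  is inside that TE by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from .annotation import AnnotationIndex, TERecord

log = logging.getLogger(__name__)


class AlignmentFormatError(ValueError):
    """Input alignments lack mate information required for pair evidence."""


@dataclass
class CallingParams:
    """Knobs shared by evidence extraction, clustering and calling.

    ``window`` (the clustering / novelty distance) is
    ``insert_mean + window_multiplier * insert_sd``: anchors of one insertion
    are spread over roughly one insert length around the breakpoint, padded
    by the insert-size spread. Truth matching in evaluation uses the
    tighter ``window_multiplier * insert_sd`` band.
    """

    level: str = "superfamily"
    min_anchor_mapq: int = 20
    min_support: int = 3
    insert_mean: float = 300.0
    insert_sd: float = 100.0
    window_multiplier: float = 3.0
    rescue_min_support: int = 1
    reference_style: str = "annotated"

    def __post_init__(self) -> None:
        for name in (
            "min_anchor_mapq",
            "min_support",
            "insert_mean",
            "insert_sd",
            "window_multiplier",
            "rescue_min_support",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"CallingParams.{name} must be > 0")
        if self.reference_style not in ("annotated", "virtual"):
            raise ValueError(
                f"reference_style must be 'annotated' or 'virtual', "
                f"got {self.reference_style!r}"
            )

    @property
    def window(self) -> float:
        return self.insert_mean + self.window_multiplier * self.insert_sd

    @property
    def match_window(self) -> float:
        return self.window_multiplier * self.insert_sd


@dataclass(frozen=True)
class AnchorEvidence:
    """One informative pair: a unique anchor plus the TE item its mate hit."""

    individual_id: str
    anchor_chrom: str
    anchor_pos: int  # 1-based leftmost mapped base of the anchor read
    anchor_strand: str  # '+' or '-'
    anchor_mapq: int
    te_record: TERecord = field(compare=False)
    te_mate_strand: str = "+"
    item: str = ""
    read_name: str = ""


def _sort_key(ev: AnchorEvidence):
    return (ev.anchor_chrom, ev.anchor_pos, ev.item, ev.read_name, ev.te_record.te_id)


def extract_evidence(
    alignments,
    index: AnnotationIndex,
    params: CallingParams,
    individual_id: str = "sample",
) -> list[AnchorEvidence]:
    """Scan one individual's alignments for anchor/TE mate-pairs.

    ``alignments`` is a SAM/BAM path or an open ``pysam.AlignmentFile``.
    Each qualifying pair yields one evidence record per distinct item its
    TE-side mate overlaps at the active hierarchy level; pairs with both
    ends in TEs, both ends outside, unmapped ends, or a sub-threshold anchor
    MAPQ yield nothing. The output is canonically sorted, so it does not
    depend on the order of input records.
    """
    own_handle = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), require_index=False)
        own_handle = True

    virtual = params.reference_style == "virtual"
    known_chroms = set(index.chrom_lengths) if index.chrom_lengths else None
    missing_chroms: set[str] = set()
    out: list[AnchorEvidence] = []
    try:
        for read in alignments.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate:
                continue
            if not read.is_paired:
                raise AlignmentFormatError(
                    f"unpaired read {read.query_name!r}: pair evidence needs "
                    "mate information"
                )
            if read.mate_is_unmapped or read.next_reference_name is None:
                continue

            chrom = read.reference_name
            start = read.reference_start  # 0-based
            end = read.reference_end or (start + (read.query_length or 1))
            mate_chrom = read.next_reference_name
            mate_start = read.next_reference_start
            mate_len = read.query_length or (end - start)
            mate_end = mate_start + mate_len
            mate_strand = "-" if read.mate_is_reverse else "+"

            if virtual:
                anchor_is_te = chrom in index.by_id
                mate_records = (
                    [index.by_id[mate_chrom]] if mate_chrom in index.by_id else []
                )
            else:
                if known_chroms is not None and chrom not in known_chroms:
                    if chrom not in missing_chroms:
                        missing_chroms.add(chrom)
                        log.warning(
                            "chromosome %s absent from annotation genome; "
                            "skipping its reads",
                            chrom,
                        )
                    continue
                anchor_is_te = index.overlaps(chrom, start, end)
                mate_records = index.overlapping(mate_chrom, mate_start, mate_end)

            # This record is the anchor of an informative pair only if it is
            # clear of all TEs while the mate touches at least one; the pair
            # is then emitted exactly once, from its anchor end.
            if anchor_is_te or not mate_records:
                continue
            if read.mapping_quality < params.min_anchor_mapq:
                continue

            seen_items: set[str] = set()
            for rec in _rank_mate_records(mate_records, mate_start, mate_end):
                item = rec.item(params.level)
                if item in seen_items:
                    continue
                seen_items.add(item)
                out.append(
                    AnchorEvidence(
                        individual_id=individual_id,
                        anchor_chrom=chrom,
                        anchor_pos=start + 1,
                        anchor_strand="-" if read.is_reverse else "+",
                        anchor_mapq=read.mapping_quality,
                        te_record=rec,
                        te_mate_strand=mate_strand,
                        item=item,
                        read_name=read.query_name,
                    )
                )
    finally:
        if own_handle:
            alignments.close()

    out.sort(key=_sort_key)
    return out


def _rank_mate_records(records, mate_start, mate_end):
    """Order candidate TE records by overlap with the mate, then te_id.

    The first record per item becomes the evidence's source copy, so the
    ordering fixes a deterministic tie-break.
    """

    def overlap(rec):
        return min(rec.end, mate_end) - max(rec.start, mate_start)

    return sorted(records, key=lambda r: (-overlap(r), r.te_id))
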