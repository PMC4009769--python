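"""High-level glue: inputs -> evidence -> population calls -> outputs."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .annotation import AnnotationIndex, parse_te_gff, DEFAULT_FEATURE_TYPES
from .calling import TEEvent
from .evidence import CallingParams, extract_evidence
from .population import PresenceMatrix, merge_population


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def chrom_lengths_from_fasta(path) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def virtual_excision_points(index: AnnotationIndex) -> dict[str, tuple[str, int]]:
    """Breakpoint of each annotated copy on TE-free chromosome coordinates.

    Computed from the annotation alone: a copy's excision point is its
    (merged-block) start minus all TE bases removed upstream of it, exactly
    mirroring how the virtual reference is cut.
    """
    points: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list] = {}
    for rec in index.records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom, recs in by_chrom.items():
        merged: list[list] = []
        for r in sorted(recs, key=lambda r: (r.start, r.end)):
            if merged and r.start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], r.end)
                merged[-1][2].append(r)
            else:
                merged.append([r.start, r.end, [r]])
        removed = 0
        for start, end, block in merged:
            for r in block:
                points[r.te_id] = (chrom, start - removed)
            removed += end - start
    return points


def load_annotation(
    gff_path,
    hierarchy_path=None,
    fasta_path=None,
    feature_types=DEFAULT_FEATURE_TYPES,
) -> AnnotationIndex:
    chrom_lengths = chrom_lengths_from_fasta(fasta_path) if fasta_path else None
    return parse_te_gff(
        gff_path,
        hierarchy_table=hierarchy_path,
        feature_types=feature_types,
        chrom_lengths=chrom_lengths,
    )


def call_population(
    alignments: dict[str, object],
    index: AnnotationIndex,
    params: CallingParams,
) -> tuple[list[TEEvent], PresenceMatrix]:
    """Run the full caller over per-individual SAM/BAM inputs.

    In virtual reference style the annotation is first re-expressed on
    TE-free coordinates so that novelty classification and the anchors share
    a coordinate system.
    """
    if params.reference_style == "virtual":
        index = index.with_virtual_loci(virtual_excision_points(index))
    per_individual = {
        ind: extract_evidence(src, index, params, individual_id=ind)
        for ind, src in alignments.items()
    }
    return merge_population(per_individual, index, params)


def call_fixture_dir(fixture_dir, params: CallingParams):
    """Call a `make_fixture` directory; returns (events, matrix, index)."""
    d = Path(fixture_dir)
    index = load_annotation(
        d / "tes.gff", d / "hierarchy.tsv", fasta_path=d / "reference.fasta"
    )
    sams = {p.stem: p for p in sorted(d.glob("*.sam"))}
    events, matrix = call_population(sams, index, params)
    return events, matrix, index
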