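"""Cluster anchor evidence and emit TE occurrence events.

Anchors supporting the same insertion pile up within roughly one insert
length of the breakpoint, so evidence is single-linkage clustered per
(chromosome, item) with linking distance ``insert_mean + k * insert_sd``
(k = 3 by default). On sorted positions single linkage reduces to one linear
sweep, giving O(n log n) overall.

Each sufficiently supported cluster becomes a :class:`TEEvent` carrying the
reported locus (median anchor position), its supporting-pair counts, an
orientation call (parallel/inverse/uncertain relative to the reference source
copy) and a novelty label: "old" when a reference locus of the same item lies
within the clustering window, "new" otherwise.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from statistics import median

from .annotation import AnnotationIndex, STRAND_UNKNOWN, TERecord
from .evidence import AnchorEvidence, CallingParams

ORIENT_PARALLEL = "parallel"
ORIENT_INVERSE = "inverse"
ORIENT_UNCERTAIN = "uncertain"


@dataclass
class Cluster:
    """Anchors of one candidate event: same chromosome, same item."""

    chrom: str
    item: str
    evidence: list[AnchorEvidence]

    def __len__(self) -> int:
        return len(self.evidence)

    def support_by_individual(self) -> Counter:
        return Counter(ev.individual_id for ev in self.evidence)


@dataclass
class TEEvent:
    """One called TE occurrence, shared across the population."""

    chrom: str
    loc: int  # 1-based reported position (median anchor)
    length: int  # length of the reference copy of the source element
    item: str
    event_type_ref: str
    non_ref_counts: int
    read_pair_support: int
    orientation: str
    p_pairs: int | None
    i_pairs: int | None
    novelty: str
    carriers: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.loc}:{self.item}"


def cluster_anchors(
    evidence: list[AnchorEvidence], params: CallingParams
) -> list[Cluster]:
    """Single-linkage clusters of anchor positions, per (chrom, item).

    Two anchors of the same chromosome and item join the same cluster when a
    chain of anchors with consecutive gaps ≤ window connects them. Evidence
    from all individuals is pooled, which is what lets low-coverage
    individuals borrow support from confident carriers later.
    """
    window = params.window
    groups: dict[tuple[str, str], list[AnchorEvidence]] = {}
    for ev in evidence:
        groups.setdefault((ev.anchor_chrom, ev.item), []).append(ev)

    clusters: list[Cluster] = []
    for (chrom, item), group in sorted(groups.items()):
        group.sort(key=lambda e: (e.anchor_pos, e.read_name, e.individual_id))
        current: list[AnchorEvidence] = [group[0]]
        for ev in group[1:]:
            if ev.anchor_pos - current[-1].anchor_pos <= window:
                current.append(ev)
            else:
                clusters.append(Cluster(chrom, item, current))
                current = [ev]
        clusters.append(Cluster(chrom, item, current))
    clusters.sort(key=lambda c: (c.chrom, c.evidence[0].anchor_pos, c.item))
    return clusters


def orientation_vote(ev: AnchorEvidence) -> str | None:
    """Vote of one pair: parallel, inverse, or None when unclassifiable.

    Mates of a fragment face each other, so for an insertion in the same
    orientation as its reference source copy the TE-side mate, expressed in
    TE-body coordinates, points opposite to the anchor; equal strands mean
    the inserted copy is flipped. The mate's genomic strand is converted to
    body coordinates by flipping when the source copy is annotated on '-'.
    Which side of the breakpoint the anchor sits on cancels out.
    """
    src_strand = ev.te_record.strand
    if src_strand == STRAND_UNKNOWN:
        return None
    mate_body = ev.te_mate_strand
    if src_strand == "-":
        mate_body = "-" if mate_body == "+" else "+"
    return ORIENT_PARALLEL if ev.anchor_strand != mate_body else ORIENT_INVERSE


def classify_orientation(
    cluster: Cluster, index: AnnotationIndex | None = None
) -> tuple[str, int, int]:
    """Majority vote over a cluster's pairs.

    Returns (orientation, parallel_count, inverse_count); ties or any pair
    against an unknown-strand source copy give "uncertain".
    """
    p = i = 0
    unknown = False
    for ev in cluster.evidence:
        vote = orientation_vote(ev)
        if vote is None:
            unknown = True
        elif vote == ORIENT_PARALLEL:
            p += 1
        else:
            i += 1
    if unknown or p == i:
        return ORIENT_UNCERTAIN, p, i
    return (ORIENT_PARALLEL if p > i else ORIENT_INVERSE), p, i


def classify_novelty(
    chrom: str,
    loc: int,
    item: str,
    index: AnnotationIndex,
    params: CallingParams,
    level: str | None = None,
) -> str:
    """"old" if a same-item reference locus lies within window of loc.

    At higher hierarchy levels *all* loci of the item count: any Copia
    called near any annotated Copia copy is old.
    """
    level = level or params.level
    window = params.window
    pos0 = loc - 1
    for ref_chrom, start, end in index.reference_loci_of_item(item, level):
        if ref_chrom != chrom:
            continue
        if start - window <= pos0 < end + window:
            return "old"
    return "new"


def format_event_type(record: TERecord) -> str:
    """Reported class string, e.g. "TE+LTR/Copia/LTR/Copia"."""
    return f"TE+{record.te_class}/{record.superfamily}/{record.te_class}/{record.superfamily}"


def source_element(cluster: Cluster) -> TERecord:
    """Most-supported source copy in a cluster; ties to smallest te_id."""
    counts = Counter(ev.te_record.te_id for ev in cluster.evidence)
    top = max(counts.values())
    te_id = min(t for t, c in counts.items() if c == top)
    for ev in cluster.evidence:
        if ev.te_record.te_id == te_id:
            return ev.te_record
    raise AssertionError("unreachable")


def call_event(
    cluster: Cluster,
    index: AnnotationIndex,
    params: CallingParams,
    carriers: dict[str, int] | None = None,
) -> TEEvent | None:
    """Turn one cluster into an event, or nothing if support is too thin.

    When ``carriers`` is given (population calling), support and counts are
    restricted to pairs from carrier individuals; otherwise the whole cluster
    counts and the min_support threshold applies to its total.
    """
    if carriers is None:
        if len(cluster) < params.min_support:
            return None
        used = cluster.evidence
        carriers = dict(cluster.support_by_individual())
    else:
        used = [ev for ev in cluster.evidence if ev.individual_id in carriers]
        if not used:
            return None

    sub = Cluster(cluster.chrom, cluster.item, used)
    loc = int(math.floor(median(ev.anchor_pos for ev in used)))
    src = source_element(sub)
    novelty = classify_novelty(cluster.chrom, loc, cluster.item, index, params)
    orientation, p, i = classify_orientation(sub, index)
    if novelty == "old" or orientation == ORIENT_UNCERTAIN:
        orientation, p_out, i_out = ORIENT_UNCERTAIN, None, None
    else:
        p_out, i_out = p, i
    return TEEvent(
        chrom=cluster.chrom,
        loc=loc,
        length=index.te_lengths.get(src.te_id, src.length),
        item=cluster.item,
        event_type_ref=format_event_type(src),
        non_ref_counts=len(carriers),
        read_pair_support=len(used),
        orientation=orientation,
        p_pairs=p_out,
        i_pairs=i_out,
        novelty=novelty,
        carriers=dict(sorted(carriers.items())),
    )
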