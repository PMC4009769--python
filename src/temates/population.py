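"""Population-level merging of TE calls and the two output files.

All individuals are called at once: evidence is pooled before clustering, so
an individual with only one or two supporting pairs at a locus still gets
genotyped as a carrier whenever some other individual supports the same
cluster confidently ("low-coverage rescue"). An event is emitted when at
least one individual reaches ``min_support`` pairs in a cluster; every
individual with at least ``rescue_min_support`` pairs there is a carrier.

Results are written as (a) a tab-separated event information file and (b) a
CSV presence/absence matrix over events x individuals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import pandas as pd

from .annotation import AnnotationIndex
from .calling import ORIENT_UNCERTAIN, TEEvent, call_event, cluster_anchors
from .evidence import AnchorEvidence, CallingParams

INFO_COLUMNS = [
    "chr",
    "loc",
    "len",
    "event_type_ref",
    "non_ref_counts",
    "anc_status",
    "read_pair_support",
    "|",
    "call_method",
    "Orientation",
    "#pPairs",
    "#iPairs",
    "new/old",
]

CALL_METHOD = "PairEndTE"
ANC_STATUS = "N"


class ConfigurationError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    """0/1 carrier matrix, events as rows, individuals as columns."""

    frame: pd.DataFrame  # index: event keys, columns: individual ids

    @property
    def events(self) -> list[str]:
        return list(self.frame.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.frame.columns)


def merge_population(
    per_individual_evidence: dict[str, list[AnchorEvidence]],
    index: AnnotationIndex,
    params: CallingParams,
) -> tuple[list[TEEvent], PresenceMatrix]:
    """Pool evidence, cluster once, and genotype every individual.

    Raises :class:`ConfigurationError` on duplicate individual ids (possible
    when the mapping is assembled from repeated CLI arguments).
    """
    individuals = list(per_individual_evidence)
    if len(set(individuals)) != len(individuals):
        raise ConfigurationError("duplicate individual_id in population input")
    if not individuals:
        raise ConfigurationError("at least one individual required")

    pooled: list[AnchorEvidence] = []
    for ind, evs in per_individual_evidence.items():
        for ev in evs:
            if ev.individual_id != ind:
                raise ConfigurationError(
                    f"evidence labelled {ev.individual_id!r} listed under "
                    f"individual {ind!r}"
                )
        pooled.extend(evs)

    events: list[TEEvent] = []
    for cluster in cluster_anchors(pooled, params):
        support = cluster.support_by_individual()
        if max(support.values()) < params.min_support:
            continue
        carriers = {
            ind: n for ind, n in support.items() if n >= params.rescue_min_support
        }
        event = call_event(cluster, index, params, carriers=carriers)
        if event is not None:
            events.append(event)

    events.sort(key=lambda e: (e.chrom, e.loc, e.item))
    frame = pd.DataFrame(
        0,
        index=[e.key for e in events],
        columns=sorted(individuals),
        dtype=int,
    )
    for e in events:
        for ind in e.carriers:
            frame.loc[e.key, ind] = 1
    return events, PresenceMatrix(frame)


# ---------------------------------------------------------------------------
# output files


def info_row(event: TEEvent) -> list[str]:
    uncertain = event.orientation == ORIENT_UNCERTAIN
    return [
        event.chrom,
        str(event.loc),
        str(event.length),
        event.event_type_ref,
        str(event.non_ref_counts),
        ANC_STATUS,
        str(event.read_pair_support),
        "|",
        CALL_METHOD,
        event.orientation,
        "" if uncertain or event.p_pairs is None else str(event.p_pairs),
        "" if uncertain or event.i_pairs is None else str(event.i_pairs),
        event.novelty,
    ]


def write_outputs(
    events: list[TEEvent], matrix: PresenceMatrix, out_prefix
) -> tuple[str, str]:
    """Write the info TSV and the presence CSV; returns the two paths."""
    info_path = f"{out_prefix}_info.tsv"
    csv_path = f"{out_prefix}_presence.csv"
    with open(info_path, "w") as fh:
        fh.write("\t".join(INFO_COLUMNS) + "\n")
        for event in events:
            fh.write("\t".join(info_row(event)) + "\n")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["event"] + matrix.individuals)
        for key, row in matrix.frame.iterrows():
            writer.writerow([key] + [int(v) for v in row])
    return info_path, csv_path


def read_info_file(path) -> list[TEEvent]:
    """Re-parse an info file into events (carrier details are not stored)."""
    events: list[TEEvent] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != INFO_COLUMNS:
            raise ValueError(f"{path}: unexpected info-file header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != len(INFO_COLUMNS):
                raise ValueError(f"{path}: malformed info line: {line!r}")
            event_type = f[3]
            # "TE+cls/sf/cls/sf" -> item at superfamily level
            parts = event_type.removeprefix("TE+").split("/")
            item = parts[1] if len(parts) >= 2 else event_type
            events.append(
                TEEvent(
                    chrom=f[0],
                    loc=int(f[1]),
                    length=int(f[2]),
                    event_type_ref=event_type,
                    item=item,
                    non_ref_counts=int(f[4]),
                    read_pair_support=int(f[6]),
                    orientation=f[9],
                    p_pairs=int(f[10]) if f[10] else None,
                    i_pairs=int(f[11]) if f[11] else None,
                    novelty=f[12],
                )
            )
    return events


def read_presence_csv(path) -> PresenceMatrix:
    frame = pd.read_csv(path, index_col=0)
    return PresenceMatrix(frame)
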