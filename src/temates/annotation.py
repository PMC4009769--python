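"""TE annotation parsing, hierarchy resolution, and interval lookup.

A TE annotation set is read from a GFF3 file plus (optionally) a plain
hierarchy table mapping each element identifier to its family, superfamily
and class/order. The resulting :class:`AnnotationIndex` answers two kinds of
question the caller needs constantly:

* which annotated TE copies (if any) overlap a genomic interval, and
* what is the name of a given element at a chosen hierarchy level
  (element < family < superfamily < class).

Coordinates are 0-based half-open internally; GFF input (1-based inclusive)
is converted on parse and converted back whenever loci are written out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: Hierarchy levels, from most to least specific.
LEVELS = ("element", "family", "superfamily", "class")

#: Feature-type filter applied to GFF rows (substring match, case-insensitive).
DEFAULT_FEATURE_TYPES = ("transposable_element",)

STRAND_UNKNOWN = "."


class AnnotationError(ValueError):
    """Malformed annotation input (bad GFF line, unresolvable identifier)."""


@dataclass(frozen=True)
class TERecord:
    """One annotated TE copy on the reference.

    ``start``/``end`` are 0-based half-open. ``strand`` is '+', '-' or '.'
    (unknown); orientation calls against unknown-strand copies are forced to
    "uncertain" downstream.
    """

    chrom: str
    start: int
    end: int
    te_id: str
    family: str
    superfamily: str
    te_class: str
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"TE {self.te_id}: empty or inverted interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        for level in LEVELS:
            if not self.item(level):
                raise AnnotationError(f"TE {self.te_id}: empty {level} name")

    @property
    def length(self) -> int:
        return self.end - self.start

    def item(self, level: str) -> str:
        """Name of this record at a hierarchy level."""
        if level == "element":
            return self.te_id
        if level == "family":
            return self.family
        if level == "superfamily":
            return self.superfamily
        if level == "class":
            return self.te_class
        raise ValueError(f"unknown hierarchy level {level!r} (choose from {LEVELS})")


class AnnotationIndex:
    """Interval index plus hierarchy lookup over a set of TE records."""

    def __init__(
        self,
        records: Iterable[TERecord],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.records: list[TERecord] = sorted(
            records, key=lambda r: (r.chrom, r.start, r.end, r.te_id)
        )
        self.by_id: dict[str, TERecord] = {}
        for rec in self.records:
            if rec.te_id in self.by_id:
                raise AnnotationError(f"duplicate te_id {rec.te_id}")
            self.by_id[rec.te_id] = rec
        self._trees: dict[str, IntervalTree] = {}
        for rec in self.records:
            self._trees.setdefault(rec.chrom, IntervalTree()).addi(
                rec.start, rec.end, rec
            )
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        # Reference copy lengths survive coordinate rewrites (virtual mode).
        self.te_lengths: dict[str, int] = {r.te_id: r.length for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, te_id: str) -> bool:
        return te_id in self.by_id

    # -- interval queries ---------------------------------------------------

    def overlapping(self, chrom: str, start: int, end: int) -> list[TERecord]:
        """All records overlapping [start, end) on chrom (0-based half-open)."""
        tree = self._trees.get(chrom)
        if tree is None or start >= end:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda r: (r.start, r.end, r.te_id))
        return hits

    def at(self, chrom: str, pos: int) -> list[TERecord]:
        """Records whose interval contains a single 0-based position."""
        return self.overlapping(chrom, pos, pos + 1)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.overlapping(chrom, start, end))

    # -- hierarchy ----------------------------------------------------------

    def item_at_level(self, te_id: str, level: str) -> str:
        try:
            rec = self.by_id[te_id]
        except KeyError:
            raise AnnotationError(f"unknown te_id {te_id!r}") from None
        return rec.item(level)

    def reference_loci_of_item(self, item: str, level: str) -> list[tuple[str, int, int]]:
        """All annotated intervals mapping to ``item`` at ``level``.

        Unknown names yield an empty list rather than an error, so novelty
        classification degrades gracefully for items never seen in the
        reference.
        """
        return [
            (r.chrom, r.start, r.end)
            for r in self.records
            if r.item(level) == item
        ]

    # -- virtual-reference support -------------------------------------------

    def with_virtual_loci(self, excision_points: Mapping[str, tuple[str, int]]) -> "AnnotationIndex":
        """Re-express reference loci on TE-free chromosome coordinates.

        After TE excision every annotated copy collapses to a single
        breakpoint; novelty classification ("is there a same-item reference
        locus near this call?") then works on the same coordinate system the
        anchors are mapped to. Each record becomes a 1 bp stub at its
        excision point; original copy lengths are preserved separately in
        ``te_lengths``.
        """
        new_records = []
        for rec in self.records:
            chrom, pos = excision_points[rec.te_id]
            new_records.append(replace(rec, chrom=chrom, start=pos, end=pos + 1))
        idx = AnnotationIndex.__new__(AnnotationIndex)
        idx.records = sorted(new_records, key=lambda r: (r.chrom, r.start, r.end, r.te_id))
        idx.by_id = {r.te_id: r for r in idx.records}
        # No TE intervals exist on TE-free chromosomes: membership queries
        # against a virtual reference are by contig name, not position.
        idx._trees = {}
        idx.chrom_lengths = self.chrom_lengths
        idx.te_lengths = dict(self.te_lengths)
        return idx


# ---------------------------------------------------------------------------
# parsing


def read_hierarchy_table(path) -> dict[str, dict[str, str]]:
    """Read a TSV mapping te_id -> family, superfamily, class.

    Expected columns: te_id, family, superfamily, class (header required;
    extra columns ignored).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"te_id", "family", "superfamily", "class"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(
            f"hierarchy table {path}: missing columns {sorted(missing)}"
        )
    out = {}
    for _, row in df.iterrows():
        out[row["te_id"]] = {
            "family": row["family"],
            "superfamily": row["superfamily"],
            "class": row["class"],
        }
    return out


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
        elif " " in part:  # GTF-ish fallback
            key, _, value = part.partition(" ")
            value = value.strip('"')
        else:
            continue
        attrs[key.strip()] = value.strip()
    return attrs


def _classify_from_attrs(attrs: Mapping[str, str]) -> tuple[str, str, str] | None:
    """Derive (family, superfamily, class) from inline GFF attributes.

    TAIR-style annotations carry a family alias plus a "Class/Superfamily"
    string such as ``LTR/Copia``; split on '/'.
    """
    lower = {k.lower(): v for k, v in attrs.items()}
    family = lower.get("family") or lower.get("alias") or lower.get("name")
    sf = lower.get("superfamily")
    cls = lower.get("class") or lower.get("order")
    if sf and "/" in sf and not cls:
        cls, _, sf = sf.partition("/")
    if family and "/" in family and not (sf and cls):
        # family attribute itself holds "LTR/Copia": use as class/superfamily
        cls2, _, sf2 = family.partition("/")
        cls = cls or cls2
        sf = sf or sf2
        family = lower.get("alias") or sf
    if family and sf and cls:
        return family, sf, cls
    return None


def parse_te_gff(
    gff_path,
    hierarchy_table=None,
    feature_types: Sequence[str] = DEFAULT_FEATURE_TYPES,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AnnotationIndex:
    """Parse TE features from a GFF3 file into an :class:`AnnotationIndex`.

    Parameters
    ----------
    gff_path:
        GFF3 file; only rows whose feature type contains one of
        ``feature_types`` (case-insensitive substring) are kept.
    hierarchy_table:
        Path to the hierarchy TSV (te_id, family, superfamily, class), or an
        already-loaded mapping. When absent, family/superfamily/class must be
        recoverable from each feature's attribute column.
    """
    if hierarchy_table is None:
        table: dict[str, dict[str, str]] = {}
    elif isinstance(hierarchy_table, Mapping):
        table = dict(hierarchy_table)
    else:
        table = read_hierarchy_table(hierarchy_table)

    wanted = tuple(ft.lower() for ft in feature_types)
    records: list[TERecord] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gff_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if not any(w in ftype.lower() for w in wanted):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"{gff_path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if start1 < 1 or end1 < start1:
                raise AnnotationError(
                    f"{gff_path}:{lineno}: bad interval {start1}-{end1}"
                )
            attrs = _parse_attributes(attr_s)
            te_id = attrs.get("ID") or attrs.get("Name")
            if not te_id:
                raise AnnotationError(
                    f"{gff_path}:{lineno}: TE feature without ID attribute"
                )
            if te_id in table:
                h = table[te_id]
                family, sf, cls = h["family"], h["superfamily"], h["class"]
            else:
                derived = _classify_from_attrs(attrs)
                if derived is None:
                    raise AnnotationError(
                        f"te_id {te_id!r} absent from hierarchy table and no "
                        f"family/superfamily attributes inline "
                        f"({gff_path}:{lineno})"
                    )
                family, sf, cls = derived
            records.append(
                TERecord(
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    te_id=te_id,
                    family=family,
                    superfamily=sf,
                    te_class=cls,
                    strand=strand if strand in "+-" else STRAND_UNKNOWN,
                )
            )
    return AnnotationIndex(records, chrom_lengths=chrom_lengths)


def write_te_gff(records: Iterable[TERecord], path) -> None:
    """Write records as GFF3 transposable_element features (1-based out)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.start, r.te_id)):
            attrs = (
                f"ID={r.te_id};family={r.family};"
                f"superfamily={r.te_class}/{r.superfamily}"
            )
            fh.write(
                f"{r.chrom}\ttemates\ttransposable_element\t{r.start + 1}\t"
                f"{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def write_hierarchy_table(records: Iterable[TERecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("te_id\tfamily\tsuperfamily\tclass\n")
        for r in sorted(records, key=lambda r: r.te_id):
            fh.write(f"{r.te_id}\t{r.family}\t{r.superfamily}\t{r.te_class}\n")
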