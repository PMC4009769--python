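"""Score TE calls against planted truth and stratify error rates by region.

A call is correct when the right superfamily is reported within three
insert-size standard deviations of the true breakpoint. Matching is greedy
nearest-first and one-to-one (each truth insertion credits at most one
call; many-to-one matching would understate false positives).

Rates follow the simulation-benchmark definitions:
``fp = false calls / all calls`` and ``fn = missed insertions / all planted``.
They can be stratified by a chromosome-region partition (chromosome arms vs
pericentromere vs centromere), since repeat-dense pericentromeric regions are
systematically harder to map.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .calling import TEEvent
from .evidence import CallingParams
from .simulate import TruthInsertion

OVERALL = "overall"


@dataclass
class RegionPartition:
    """Labelled, disjoint intervals per chromosome (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, path) -> "RegionPartition":
        intervals: dict[str, list[tuple[int, int, str]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"partition BED needs 4 columns, got: {line!r}")
                intervals.setdefault(f[0], []).append((int(f[1]), int(f[2]), f[3]))
        for chrom in intervals:
            intervals[chrom].sort()
        return cls(intervals)

    @classmethod
    def single_class(cls, chrom_lengths: dict[str, int], label: str = "arm") -> "RegionPartition":
        return cls({c: [(0, n, label)] for c, n in chrom_lengths.items()})

    @classmethod
    def arabidopsis_default(cls) -> "RegionPartition":
        """Approximate arm/pericentromere/centromere partition for TAIR10."""
        ref = importlib.resources.files("temates.data").joinpath(
            "arabidopsis_regions.tsv"
        )
        intervals: dict[str, list[tuple[int, int, str]]] = {}
        for line in ref.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            chrom, start, end, label = line.split("\t")
            intervals.setdefault(chrom, []).append((int(start), int(end), label))
        return cls(intervals)

    def label_of(self, chrom: str, pos1: int) -> str:
        """Region label of a 1-based position; unknown regions label 'arm'."""
        for start, end, label in self.intervals.get(chrom, []):
            if start <= pos1 - 1 < end:
                return label
        return "arm"


@dataclass
class RegionScores:
    n_truth: int = 0
    n_calls: int = 0
    n_correct: int = 0
    n_matched_truth: int = 0

    @property
    def fp_rate(self) -> float:
        return (self.n_calls - self.n_correct) / self.n_calls if self.n_calls else 0.0

    @property
    def fn_rate(self) -> float:
        if not self.n_truth:
            return 0.0
        return (self.n_truth - self.n_matched_truth) / self.n_truth


@dataclass
class EvaluationResult:
    per_region: dict[str, RegionScores]

    @property
    def overall(self) -> RegionScores:
        return self.per_region[OVERALL]


def match_calls(
    calls: list[TEEvent],
    truth: list[TruthInsertion],
    params: CallingParams,
    truth_items: list[str] | None = None,
) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching of calls to truth.

    A (call, truth) pair is admissible iff the items agree and the distance
    |call.loc - truth.pos| is at most ``window_multiplier * insert_sd``
    (boundary inclusive). ``truth_items`` defaults to each insertion's
    superfamily, matching superfamily-level calling.
    """
    if truth_items is None:
        truth_items = [t.superfamily for t in truth]
    window = params.match_window
    candidates: list[tuple[int, int, int]] = []
    for ci, call in enumerate(calls):
        for ti, ins in enumerate(truth):
            if call.chrom != ins.chrom or call.item != truth_items[ti]:
                continue
            d = abs(call.loc - ins.pos)
            if d <= window:
                candidates.append((d, ci, ti))
    candidates.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matching: list[tuple[int, int]] = []
    for _, ci, ti in candidates:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matching.append((ci, ti))
    return sorted(matching)


def error_rates(
    matching: list[tuple[int, int]],
    truth: list[TruthInsertion],
    calls: list[TEEvent],
    partition: RegionPartition | None = None,
) -> EvaluationResult:
    """Per-region and overall FP/FN rates from a matching."""
    scores: dict[str, RegionScores] = {OVERALL: RegionScores()}

    def bucket(label: str) -> RegionScores:
        return scores.setdefault(label, RegionScores())

    matched_calls = {ci for ci, _ in matching}
    matched_truth = {ti for _, ti in matching}

    for ci, call in enumerate(calls):
        label = partition.label_of(call.chrom, call.loc) if partition else "arm"
        for s in (scores[OVERALL], bucket(label)):
            s.n_calls += 1
            if ci in matched_calls:
                s.n_correct += 1
    for ti, ins in enumerate(truth):
        label = partition.label_of(ins.chrom, ins.pos) if partition else "arm"
        for s in (scores[OVERALL], bucket(label)):
            s.n_truth += 1
            if ti in matched_truth:
                s.n_matched_truth += 1
    return EvaluationResult(per_region=scores)


def write_report(result: EvaluationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tn_truth\tn_calls\tn_correct\tfp_rate\tfn_rate\n")
        for label in sorted(result.per_region):
            s = result.per_region[label]
            fh.write(
                f"{label}\t{s.n_truth}\t{s.n_calls}\t{s.n_correct}\t"
                f"{s.fp_rate:.6f}\t{s.fn_rate:.6f}\n"
            )
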