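# Methods

## Evidence model

The caller consumes coordinate-mapped paired-end alignments (SAM/BAM via
pysam) and a TE annotation (GFF3 plus a hierarchy table mapping each element
to family, superfamily and class/order). A pair is *informative* when one
end — the anchor — maps entirely outside every annotated TE with mapping
quality at least `min_anchor_mapq`, and the other end overlaps at least one
annotated TE copy by ≥ 1 bp. Rationale for the asymmetry: reads inside TE
bodies multi-map among near-identical copies, so no MAPQ requirement is
placed on the TE-side mate; the anchor, by contrast, must be trustworthy
because it alone fixes the locus. An anchor touching a TE by even 1 bp is
disqualified (strictest reading of "outside all TEs"). Secondary,
supplementary and duplicate-flagged records are ignored. If the TE-side
mate overlaps several records, one evidence item is emitted per *distinct*
item at the active hierarchy level (the ambiguity is resolved by cluster
support, not per read); the per-item source record is the one with the
largest mate overlap, ties to the smallest te_id.

Two reference styles are supported. With `annotated`, TE membership is an
interval query against the annotation (intervaltree-backed, verified against
a linear scan). With `virtual`, reads were mapped to a reference whose TE
intervals were excised into contigs named by te_id; a mate on such a contig
is inside that TE by construction, and the annotation's reference loci are
re-expressed as excision breakpoints on TE-free coordinates so that novelty
classification shares the anchors' coordinate system.

## Clustering and event calling

Evidence from the whole population is pooled and single-linkage clustered
per (chromosome, item) with linking distance

    window = insert_mean + window_multiplier × insert_sd    (default 300 + 3×100 = 600 bp)

Anchors of one insertion sit within roughly one insert length of the
breakpoint on either side; the kσ term absorbs insert-size spread. On sorted
positions single linkage is a linear sweep; the sort dominates at
O(n log n). The sweep is property-tested against an independent
connected-components oracle.

An event is emitted when at least one individual contributes `min_support`
pairs (default 3) to a cluster; every individual with ≥ `rescue_min_support`
pairs (default 1) is then a carrier. This pooled genotyping is what lets
low-coverage individuals inherit confident events from the population.
Reported fields:

- **loc** — floored median of the carrier anchors' 1-based positions; the
  median is robust to one-sided anchor pileups, and downstream matching
  tolerates the residual offset.
- **len** — length of the annotated reference copy of the cluster's
  most-supported source element (ties to smallest te_id). This is an
  interpretation choice: at higher hierarchy levels the "corresponding
  reference event" is ambiguous, and only this field depends on it.
- **orientation** — each pair votes by geometry: mates of a fragment face
  each other, so for an insertion in the same orientation as its source copy
  the TE-side mate, expressed in TE-body coordinates (its genomic strand,
  flipped when the source copy is annotated on '−'), points opposite to the
  anchor. Equal anchor/mate-body strands therefore vote *inverse*, unequal
  vote *parallel*; which flank the anchor sits on cancels out of the rule.
  Majority wins; a tie, any vote against an unknown-strand source copy, or
  an *old* event gives *uncertain* with the pair counts suppressed in the
  output. The rule was validated empirically: on simulated individuals the
  call equals (planted strand == source strand ? parallel : inverse) for
  every event.
- **novelty** — *old* iff some reference locus of the same item (all loci of
  the item at the active level) lies within `window` of loc; *new*
  otherwise.

Outputs are a tab-separated info file (constant `call_method=PairEndTE`,
`anc_status=N`; a literal `|` column stands in for four unused legacy
fields) and a CSV presence/absence matrix keyed by `(chrom, loc, item)`.

## Simulation harness

`build_virtual_reference` excises every annotated TE (overlapping records
merged into one excision; each record's contig is sliced from the merged
block, so base count is conserved exactly for non-overlapping annotations).
`plant_insertions` reinserts sampled TE contigs (without replacement) at
uniform breakpoints on the TE-free chromosomes, with random strand;
`mutate_snps` changes exactly n distinct positions to a different base
(uniform placement — the real mutational landscape is not modelled).
`simulate_read_pairs` draws `round(coverage × L / (2 × read_length))`
inner-facing pairs with Normal(insert_mean, insert_sd) fragment lengths
truncated below at 2×read_length, and substitution errors at
`base_error_rate` (no indels or quality profiles).

Instead of an external aligner, a truth SAM places each read at its true
origin projected onto the virtual reference: reads are assigned to the
mosaic block (flank segment or planted TE body) holding the majority of
their bases, with MAPQ 60 on TE-free chromosomes and MAPQ 0 on TE contigs —
mimicking the unique-flank / multi-mapping-body behaviour the method relies
on without reproducing any specific aligner. A `call` run on real alignments
produced by an external aligner against the written virtual-reference
FASTAs is supported identically (`--reference-style virtual`); no test
requires one. Consequences for interpretation: truth alignments contain no
mapping errors, chimeras or soft-clips, so the simulated false-positive
floor is optimistic relative to real data; FN behaviour (support thinning at
low coverage, anchor-space loss at long reads relative to the insert) is
representative.

Everything is deterministic under a fixed seed (numpy Generator seeded with
`[seed, stream]` sequences); fixture directories are byte-identical per
seed.

## Evaluation

A call matches a truth insertion iff the superfamily agrees and
`|loc − pos| ≤ window_multiplier × insert_sd` (3σ = 300 bp by default;
boundary inclusive). Note this matching window is deliberately *tighter*
than the clustering window (no insert_mean term). Matching is greedy
nearest-first and one-to-one. `fp = (calls − matched calls)/calls` (0 when
there are no calls), `fn = (truth − matched truth)/truth`. Rates can be
stratified by a user BED of region labels; an approximate arm /
pericentromere / centromere partition for *A. thaliana* TAIR10 ships as a
convenience data file (boundaries are rounded estimates).

## Diversity statistic

For an event with carrier frequency p̂ among n individuals, the mean number
of pairwise differences is `2·p̂·(1−p̂)·n/(n−1)` — algebraically identical to
averaging the 0/1 difference over all unordered pairs, which is kept as a
brute-force oracle (agreement to 1e−12 on random matrices). Events enter
20 kb windows by point locus (lengths unweighted); window values are
normalized per bp. The TE-vs-SNP window correlation (Pearson default,
Spearman optional) skips any window with zero events in either track and is
reported as undefined below three surviving windows. SNP input is a plain
genotype TSV; a cyvcf2-based VCF reader is available as an optional extra.

## Problem sizes and defaults

The shipped study scales are desk-sized by design: `default` is a 200 kb
two-chromosome genome with 20 annotated TE copies (800–3000 bp) across four
superfamilies, three individuals with 10 planted insertions each, SNPs at
0.4% of the genome, 20× coverage, 100 bp reads, 300±100 bp inserts — the
same regime, scaled down, as a population-resequencing study. Trend sweeps
use a 100 kb genome with 12 copies and 8 insertions over five seeds. At
these sizes the full suite and the acceptance script each complete in well
under a minute per scenario.

## Known limitations

- Two same-item insertions closer than one clustering window collapse into
  a single event (population pooling makes this more likely); the worked
  example in the README shows one such merge.
- No split-read evidence and no negative-support counting, so breakpoints
  are insert-resolution and homozygous-absence cannot be asserted.
- Reference copies are not absence-typed; *old* calls only say the item is
  already annotated nearby.
- The simulator's uniform SNP placement, absence of indels, and error-free
  truth alignments make simulated FP rates a lower bound for real data.
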