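# temates

Population-scale calling of transposable-element (TE) occurrences from
paired-end sequencing data, for groups studying TE mobility in resequenced
populations (plant or otherwise) where the reference genome already carries a
TE annotation.

## The problem and the method

TEs are highly similar to each other, so short reads landing *inside* a TE
body rarely map uniquely — but the flanks of a new insertion are ordinary
unique sequence. `temates` therefore collects **anchor pairs**: mate-pairs in
which one read maps with good quality (MAPQ ≥ 20 by default) outside every
annotated TE while its mate lands inside an annotated TE copy. The anchor
pins the insertion's flank; the TE-side mate names *what* jumped there. To
avoid splintering one insertion into many calls against near-identical
elements, the TE-side hit is expressed at a configurable hierarchy level —
element < family < superfamily < class — trading specificity for reliability.

Anchors are single-linkage clustered per (chromosome, item) with linking
distance `μ + kσ`, where μ, σ are the insert-size mean and standard deviation
and k = 3; on sorted positions this is a linear sweep, O(n log n) overall.
Each sufficiently supported cluster becomes an event with:

- `loc` — median anchor position,
- `read_pair_support` — total supporting pairs over all carriers,
- orientation — *parallel* / *inverse* / *uncertain* by majority vote of the
  pairs' geometry against the source copy's annotated strand,
- novelty — *old* if a reference locus of the same item lies within the
  clustering window, *new* otherwise.

The whole population is called at once: evidence is pooled before
clustering, so an individual with a single supporting pair at a locus is
still genotyped as a carrier when another individual supports the same
cluster with ≥ `min_support` (default 3) pairs.

A windowed diversity statistic is included for downstream analysis: the mean
pairwise difference per bp between individuals' event presence/absence
profiles, `π_w = Σ_events 2p̂(1−p̂)·n/(n−1) / w` per window of w = 20 kb, plus
a TE-vs-SNP window correlation that skips windows empty in either track.

A simulation/validation harness mirrors the benchmark design: annotated TEs
are excised into a **virtual reference** (TE-free chromosomes + one contig
per TE copy), reinserted at random loci in a virtual individual, SNPs are
added (0.4% of the genome by default), and inner-facing read pairs are drawn
with truth alignments, so the caller can be scored without an external
aligner. A call is *correct* when the right superfamily is reported within
3σ of the planted breakpoint; `fp = false calls / all calls`,
`fn = missed insertions / all planted`.

## Worked example

Generate a small synthetic study (two chromosomes, annotated TE copies from
four superfamilies, two individuals with planted insertions and truth
alignments), call it, and score it:

```bash
temates make-fixture --out-dir fx --seed 11 --scale mini
temates call --gff fx/tes.gff --hierarchy fx/hierarchy.tsv \
    --reference-style virtual \
    --bam ind1=fx/ind1.sam --bam ind2=fx/ind2.sam --out-prefix fx/calls
temates evaluate --calls fx/calls_info.tsv --truth fx/truth.tsv --out fx/report.tsv
```

The info file (`fx/calls_info.tsv`) starts

```
chr	loc	len	event_type_ref	non_ref_counts	anc_status	read_pair_support	|	call_method	Orientation	#pPairs	#iPairs	new/old
chr1	8110	662	TE+LTR/Gypsy/LTR/Gypsy	1	N	42	|	PairEndTE	parallel	42	0	new
chr1	15111	726	TE+LTR/Copia/LTR/Copia	1	N	38	|	PairEndTE	inverse	0	38	new
chr1	16526	539	TE+LTR/Copia/LTR/Copia	1	N	46	|	PairEndTE	inverse	0	46	new
```

Reading the second row: a Copia insertion at chr1:15111 carried by 1 of the
2 individuals, supported by 38 read pairs, all voting that the inserted copy
is inverted relative to its reference source copy, at a locus with no
annotated Copia nearby (*new*). The companion `fx/calls_presence.csv` is the
0/1 events × individuals matrix. The evaluation report reads

```
region	n_truth	n_calls	n_correct	fp_rate	fn_rate
arm	8	7	7	0.000000	0.125000
overall	8	7	7	0.000000	0.125000
```

— no false calls, and 7 of the 8 planted insertions recovered under the
3σ/superfamily correctness rule. The one miss is instructive: two Gypsy
insertions from different individuals landed 645 bp apart on chr2, inside
one clustering window, so population pooling merged them into a single
event — the price of calling at superfamily level (a single call, here at
chr2:3022, can only match one truth breakpoint).

## Not in scope

De-novo TE discovery, split-read evidence, negative (contradicting) pair
support, absence typing of reference copies, and VCF emission. See
`docs/methods.md` for the model details and limitations.
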