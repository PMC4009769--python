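"""Desk-scale synthetic study: genome, annotation, individuals, truth reads.

``make_fixture`` emulates the full set of inputs the caller needs — a small
multi-chromosome genome with annotated TE copies across several
superfamilies, a hierarchy table, and per-individual truth alignments of
simulated paired reads against the virtual reference — entirely from a seed.
It exists both as a CLI subcommand and as the generator behind the test
suite and worked examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationIndex, TERecord, write_hierarchy_table, write_te_gff
from .simulate import (
    SampleGenome,
    SimParams,
    VirtualReference,
    annotate_truth,
    build_virtual_reference,
    mutate_snps,
    plant_insertions,
    simulate_read_pairs,
    write_truth_sam,
    write_truth_tsv,
)

# superfamily -> (class/order, family name stems); names as used in A. thaliana
SUPERFAMILIES = {
    "Copia": ("LTR", "ATCOPIA"),
    "Gypsy": ("LTR", "ATGP"),
    "Helitron": ("RC", "ATREP"),
    "MuDR": ("DNA", "ATMU"),
    "HAT": ("DNA", "ATHAT"),
    "L1": ("LINE", "ATLINE"),
}

SCALES = {
    # chrom_lengths, n_tes, n_individuals, insertions_per_individual,
    # snp_rate, te_length_range
    "default": ([100_000, 100_000], 20, 3, 10, 0.004, (800, 3000)),
    "mini": ([25_000, 15_000], 10, 2, 4, 0.004, (500, 1200)),
}


@dataclass
class Fixture:
    """In-memory fixture: reference, annotation, and per-individual samples."""

    genome: dict[str, str]
    index: AnnotationIndex
    virtual: VirtualReference
    samples: dict[str, SampleGenome] = field(default_factory=dict)
    reads: dict[str, list] = field(default_factory=dict)
    sim_params: SimParams | None = None


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_reference(
    rng: np.random.Generator,
    chrom_lengths: list[int],
    n_tes: int,
    superfamilies: list[str] | None = None,
    te_length_range: tuple[int, int] = (800, 3000),
    pad: int = 1000,
) -> tuple[dict[str, str], AnnotationIndex]:
    """Random genome with non-overlapping annotated TE copies embedded.

    Each TE copy gets a unique random body sequence, so truth projection is
    unambiguous. Copies are spread round-robin over at least four
    superfamilies and assigned two families per superfamily.
    """
    sfs = superfamilies or ["Copia", "Gypsy", "Helitron", "MuDR"]
    chroms = {f"chr{i + 1}": random_sequence(rng, ln) for i, ln in enumerate(chrom_lengths)}

    # choose non-overlapping slots, padded so anchors have room around TEs
    records: list[TERecord] = []
    per_chrom = {c: [] for c in chroms}
    for k in range(n_tes):
        sf = sfs[k % len(sfs)]
        cls, stem = SUPERFAMILIES[sf]
        family = f"{stem}{1 + (k // len(sfs)) % 2}"
        te_len = int(rng.integers(te_length_range[0], te_length_range[1] + 1))
        for _ in range(500):
            chrom = str(rng.choice(sorted(chroms)))
            L = len(chroms[chrom])
            if L < te_len + 2 * pad:
                continue
            start = int(rng.integers(pad, L - te_len - pad))
            end = start + te_len
            if all(e <= start - pad or s >= end + pad for s, e in per_chrom[chrom]):
                per_chrom[chrom].append((start, end))
                records.append(
                    TERecord(
                        chrom=chrom,
                        start=start,
                        end=end,
                        te_id=f"{chrom.upper()}TE{k + 1:04d}",
                        family=family,
                        superfamily=sf,
                        te_class=cls,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
                break
        else:
            raise RuntimeError("could not place all TE copies; genome too small")

    # splice unique TE bodies into the genome at the annotated slots
    genome = {}
    for chrom, seq in chroms.items():
        arr = list(seq)
        for rec in records:
            if rec.chrom != chrom:
                continue
            body = random_sequence(rng, rec.length)
            arr[rec.start : rec.end] = list(body)
        genome[chrom] = "".join(arr)

    index = AnnotationIndex(records, chrom_lengths={c: len(s) for c, s in genome.items()})
    return genome, index


def simulate_individual(
    virtual: VirtualReference,
    index: AnnotationIndex,
    n_insertions: int,
    sim_params: SimParams,
    rng: np.random.Generator,
    snp_rate: float = 0.0,
) -> tuple[SampleGenome, list]:
    """Plant insertions, mutate SNPs, and draw read pairs for one individual."""
    sample = plant_insertions(virtual, n_insertions, rng)
    annotate_truth(sample, index)
    if snp_rate > 0:
        n_snps = int(round(snp_rate * sample.total_length))
        sample.sequences = mutate_snps(sample.sequences, n_snps, rng)
    pairs = simulate_read_pairs(sample, sim_params, rng)
    return sample, pairs


def build_fixture(
    seed: int,
    scale: str = "default",
    sim_params: SimParams | None = None,
    n_individuals: int | None = None,
    insertions_per_individual: int | None = None,
) -> Fixture:
    """Deterministic in-memory fixture (no files)."""
    chrom_lengths, n_tes, n_ind, n_ins, snp_rate, te_len_range = SCALES[scale]
    n_ind = n_individuals if n_individuals is not None else n_ind
    n_ins = (
        insertions_per_individual
        if insertions_per_individual is not None
        else n_ins
    )
    sim_params = sim_params or SimParams(seed=seed)
    rng = np.random.default_rng([seed, 0])
    genome, index = make_reference(rng, chrom_lengths, n_tes, te_length_range=te_len_range)
    virtual = build_virtual_reference(genome, index)
    fixture = Fixture(genome=genome, index=index, virtual=virtual, sim_params=sim_params)
    for i in range(n_ind):
        ind_rng = np.random.default_rng([seed, 1 + i])
        sample, pairs = simulate_individual(
            virtual, index, n_ins, sim_params, ind_rng, snp_rate=snp_rate
        )
        fixture.samples[f"ind{i + 1}"] = sample
        fixture.reads[f"ind{i + 1}"] = pairs
    return fixture


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_fixture(
    out_dir,
    seed: int,
    scale: str = "default",
    sim_params: SimParams | None = None,
    n_individuals: int | None = None,
    insertions_per_individual: int | None = None,
) -> Path:
    """Write a complete fixture directory; byte-identical per seed.

    Contents: reference.fasta, tes.gff, hierarchy.tsv, virtual_reference
    FASTAs, one truth SAM per individual, per-individual and combined truth
    TSVs, and a manifest of the parameters used.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture = build_fixture(
        seed,
        scale=scale,
        sim_params=sim_params,
        n_individuals=n_individuals,
        insertions_per_individual=insertions_per_individual,
    )
    write_fasta(fixture.genome, out / "reference.fasta")
    write_te_gff(fixture.index.records, out / "tes.gff")
    write_hierarchy_table(fixture.index.records, out / "hierarchy.tsv")
    write_fasta(fixture.virtual.te_free, out / "virtual_chromosomes.fasta")
    write_fasta(fixture.virtual.contigs, out / "virtual_te_contigs.fasta")

    combined = []
    for ind in sorted(fixture.samples):
        sample = fixture.samples[ind]
        write_truth_sam(fixture.reads[ind], fixture.virtual, out / f"{ind}.sam")
        write_truth_tsv(sample.truth, out / f"{ind}.truth.tsv")
        combined.extend((ind, t) for t in sample.truth)
    with open(out / "truth.tsv", "w") as fh:
        fh.write("individual\tchrom\tpos\tte_id\tsuperfamily\tstrand\n")
        for ind, t in combined:
            fh.write(f"{ind}\t{t.chrom}\t{t.pos}\t{t.te_id}\t{t.superfamily}\t{t.strand}\n")

    sp = fixture.sim_params
    manifest = {
        "seed": seed,
        "scale": scale,
        "individuals": sorted(fixture.samples),
        "coverage": sp.coverage,
        "read_length": sp.read_length,
        "insert_mean": sp.insert_mean,
        "insert_sd": sp.insert_sd,
        "base_error_rate": sp.base_error_rate,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
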