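"""Windowed pairwise-difference diversity on presence/absence matrices.

For a biallelic presence column with carrier frequency p-hat among n
individuals, the mean number of pairwise differences is
``2 * p * (1 - p) * n / (n - 1)`` (the unbiased per-site heterozygosity).
Summing over the events falling in a fixed-size window and normalizing by
the window length (default 20 kb, reported per bp) gives a diversity track
comparable between TE events and SNPs. Events enter windows by their point
locus; event lengths are deliberately not weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .population import PresenceMatrix

DEFAULT_WINDOW = 20_000


@dataclass
class DiversityTrack:
    """Per-window diversity values, normalized to 1 bp."""

    window_size: int
    frame: pd.DataFrame  # columns: chrom, start (0-based), value, n_events


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    n_windows: int
    defined: bool


def pairwise_diversity(
    matrix: PresenceMatrix | pd.DataFrame | np.ndarray,
    positions: list[tuple[str, int]],
    window_size: int = DEFAULT_WINDOW,
    chrom_lengths: dict[str, int] | None = None,
) -> DiversityTrack:
    """Mean pairwise difference per bp in non-overlapping windows.

    ``positions`` gives each event's (chrom, 1-based locus), one per matrix
    row. Windows run from 0 to the chromosome length (or the last event when
    lengths are not provided); windows without events are kept with value 0
    so that downstream correlation can apply its skip rule.
    """
    if isinstance(matrix, PresenceMatrix):
        values = matrix.frame.to_numpy(dtype=float)
    elif isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or len(positions) != values.shape[0]:
        raise ValueError("matrix rows must correspond one-to-one with positions")
    n = values.shape[1]
    if n < 2:
        raise ValueError("pairwise diversity needs at least 2 individuals")

    p_hat = values.sum(axis=1) / n
    per_event = 2.0 * p_hat * (1.0 - p_hat) * n / (n - 1)

    sums: dict[tuple[str, int], list[float]] = {}
    for (chrom, loc), contrib in zip(positions, per_event):
        w = (int(loc) - 1) // window_size
        cell = sums.setdefault((chrom, w), [0.0, 0])
        cell[0] += float(contrib)
        cell[1] += 1

    chrom_max: dict[str, int] = {}
    if chrom_lengths:
        for chrom, ln in chrom_lengths.items():
            chrom_max[chrom] = (max(ln - 1, 0)) // window_size
    else:
        for chrom, loc in positions:
            w = (int(loc) - 1) // window_size
            chrom_max[chrom] = max(chrom_max.get(chrom, 0), w)

    rows = []
    for chrom in sorted(chrom_max):
        for w in range(chrom_max[chrom] + 1):
            total, count = sums.get((chrom, w), (0.0, 0))
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * window_size,
                    "value": total / window_size,
                    "n_events": count,
                }
            )
    return DiversityTrack(window_size=window_size, frame=pd.DataFrame(rows))


def pairwise_diversity_bruteforce(
    values: np.ndarray,
) -> float:
    """All-pairs oracle for one window: mean event-count difference per pair.

    Exists as an independent cross-check of the frequency formula; quadratic
    in the number of individuals.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    total = 0.0
    pairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            total += float(np.sum(values[:, a] != values[:, b]))
            pairs += 1
    return total / pairs if pairs else 0.0


def window_correlation(
    track_a: DiversityTrack,
    track_b: DiversityTrack,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation of two diversity tracks over shared windows.

    Windows where either track has zero events are skipped. With fewer than
    three surviving windows the correlation is undefined and reported as
    such (NaN values, defined=False).
    """
    if track_a.window_size != track_b.window_size:
        raise ValueError("tracks must share the window size")
    a = track_a.frame.set_index(["chrom", "start"])
    b = track_b.frame.set_index(["chrom", "start"])
    joined = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    joined = joined[(joined["n_events_a"] > 0) & (joined["n_events_b"] > 0)]
    n = len(joined)
    if n < 3:
        return CorrelationResult(float("nan"), float("nan"), n, False)
    x = joined["value_a"].to_numpy()
    y = joined["value_b"].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(float("nan"), float("nan"), n, False)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(r), float(p), n, True)


# ---------------------------------------------------------------------------
# genotype inputs for the SNP track


def load_genotype_tsv(path) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Load a per-site genotype matrix: columns chrom, pos, <individuals...>.

    Genotypes are 0/1 presence of the non-reference allele. Returns the
    matrix (sites x individuals) and the site positions, ready for
    :func:`pairwise_diversity`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"}.issubset(df.columns):
        raise ValueError(f"{path}: genotype TSV needs 'chrom' and 'pos' columns")
    positions = [(str(c), int(p)) for c, p in zip(df["chrom"], df["pos"])]
    matrix = df.drop(columns=["chrom", "pos"])
    return matrix, positions


def load_genotype_vcf(path) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Optional VCF loader (biallelic sites; any ALT dosage counts as 1)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, positions = [], []
    for variant in vcf:
        gts = [1 if g[0] > 0 or g[1] > 0 else 0 for g in variant.genotypes]
        rows.append(gts)
        positions.append((variant.CHROM, variant.POS))
    return pd.DataFrame(rows, columns=samples), positions
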