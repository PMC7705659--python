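"""Assembly/annotation summary statistics and a k-mer genome-size estimator.

Conventions: N50 is the smallest length in the minimal descending-sorted
prefix of scaffold lengths whose sum reaches half the assembly total, and L50
is that prefix's size; the GC denominator excludes ambiguous bases;
percentages are rounded half-up to two decimals at presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (display convention for percentages/means)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """``part/whole`` as a percentage rounded half-up to ``ndigits``."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    return round_half_up(100.0 * part / whole, ndigits)


@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    longest_bp: int
    n50: int
    l50: int
    gc_fraction: float
    anchored_bp: int
    anchored_fraction: float  # 0..1; use .anchored_pct for display

    @property
    def anchored_pct(self) -> float:
        return percent(self.anchored_bp, self.total_bp)


@dataclass
class AnnotationStats:
    n_genes: int
    mean_gene_len: float
    mean_cds_len: float
    n_exons: int
    mean_exons_per_gene: float
    pct_on_chromosomes: float  # percentage, 2 dp


# ------------------------------------------------------------------ assembly

def n50_l50(lengths: Iterable[int]) -> tuple[int, int]:
    """(N50, L50) of a multiset of sequence lengths.

    Smallest member of the minimal descending prefix with cumulative sum
    >= total/2, and the prefix size.
    """
    ls = sorted((int(x) for x in lengths), reverse=True)
    if not ls:
        raise ValueError("empty length set")
    half = sum(ls) / 2.0
    cum = 0
    for i, length in enumerate(ls):
        cum += length
        if cum >= half:
            return length, i + 1
    raise AssertionError("unreachable")


def assembly_stats(
    sequences: Mapping[str, str] | str | Path,
    chromosome_ids: Iterable[str] = (),
) -> AssemblyStats:
    """Summary statistics of a scaffold set.

    ``sequences`` is an ``{id: sequence}`` mapping or a FASTA path;
    ``chromosome_ids`` marks the scaffolds counted as anchored.
    """
    if not isinstance(sequences, Mapping):
        from .io import read_fasta

        sequences = read_fasta(sequences)
    if not sequences:
        raise ValueError("empty FASTA")
    lengths = {name: len(seq) for name, seq in sequences.items()}
    total = sum(lengths.values())
    n50, l50 = n50_l50(lengths.values())
    gc = at = 0
    for seq in sequences.values():
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    chrom = set(chromosome_ids)
    anchored = sum(l for name, l in lengths.items() if name in chrom)
    return AssemblyStats(
        n_scaffolds=len(sequences),
        total_bp=total,
        longest_bp=max(lengths.values()),
        n50=n50,
        l50=l50,
        gc_fraction=gc / (gc + at) if gc + at else float("nan"),
        anchored_bp=anchored,
        anchored_fraction=anchored / total,
    )


# ------------------------------------------------------------------ annotation

def annotation_stats(
    genes: Sequence[GeneModel], chromosome_ids: Iterable[str]
) -> AnnotationStats:
    """Gene-model summary; exact means, percentages to 2 dp (half-up)."""
    if not genes:
        raise ValueError("no genes")
    chrom = set(chromosome_ids)
    n = len(genes)
    n_exons = sum(g.exon_count or 0 for g in genes)
    on_chrom = sum(1 for g in genes if g.seq_id in chrom)
    cds_lens = [len(g.cds) for g in genes if g.cds]
    return AnnotationStats(
        n_genes=n,
        mean_gene_len=sum(g.length for g in genes) / n,
        mean_cds_len=sum(cds_lens) / len(cds_lens) if cds_lens else float("nan"),
        n_exons=n_exons,
        mean_exons_per_gene=n_exons / n,
        pct_on_chromosomes=percent(on_chrom, n),
    )


def annotation_stats_from_counts(
    n_genes: int, n_exons: int, n_on_chromosomes: int
) -> AnnotationStats:
    """Derived annotation statistics from printed summary counts alone."""
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    return AnnotationStats(
        n_genes=n_genes,
        mean_gene_len=float("nan"),
        mean_cds_len=float("nan"),
        n_exons=n_exons,
        mean_exons_per_gene=n_exons / n_genes,
        pct_on_chromosomes=percent(n_on_chromosomes, n_genes),
    )


# ------------------------------------------------------------------ k-mer size

def kmer_genome_size(histogram: pd.DataFrame | Sequence[tuple[int, int]]) -> dict:
    """Peak-ratio genome-size estimate from a k-mer depth histogram.

    The error cloud of sequencing-error k-mers dominates low depths; the
    first local minimum of count-vs-depth separates it from the signal. The
    estimate is (total k-mer volume beyond the cutoff) / (homozygous peak
    depth). Returns a dict with ``genome_size_bp``, ``error_cutoff`` and
    ``peak_depth``.
    """
    if isinstance(histogram, pd.DataFrame):
        df = histogram[["depth", "count"]].astype(np.int64)
    else:
        df = pd.DataFrame(histogram, columns=["depth", "count"], dtype=np.int64)
    df = df.sort_values("depth").reset_index(drop=True)
    if (df["depth"] < 1).any():
        raise ValueError("depths must be >= 1")
    counts = df["count"].to_numpy()
    depths = df["depth"].to_numpy()
    cutoff_idx = None
    for i in range(1, len(counts) - 1):
        if counts[i] <= counts[i - 1] and counts[i] < counts[i + 1]:
            cutoff_idx = i
            break
    if cutoff_idx is None:
        raise ValueError("no error/signal separation (no interior local minimum)")
    sub = slice(cutoff_idx, None)
    peak_pos = int(np.argmax(counts[sub])) + cutoff_idx
    peak_depth = int(depths[peak_pos])
    volume = int((depths[sub] * counts[sub]).sum())
    return {
        "genome_size_bp": volume / peak_depth,
        "error_cutoff": int(depths[cutoff_idx]),
        "peak_depth": peak_depth,
    }


def simulate_kmer_histogram(
    genome_size_bp: int,
    coverage: float = 50.0,
    error_kmers: int | None = None,
    seed: int = 0,
    max_depth: int = 150,
) -> pd.DataFrame:
    """Synthetic k-mer histogram: Poisson(coverage) signal + low-depth error spike.

    A fixture generator for exercising :func:`kmer_genome_size` at a known
    genome size without touching read data.
    """
    rng = np.random.default_rng(seed)
    if error_kmers is None:
        error_kmers = genome_size_bp * 2
    depths = np.arange(1, max_depth + 1)
    from scipy.stats import poisson

    signal = genome_size_bp * poisson.pmf(depths, coverage)
    # error k-mers: geometric-ish decay concentrated at depth 1-3
    error = error_kmers * 0.6 ** (depths - 1) * 0.4
    counts = np.rint(signal + error).astype(np.int64)
    noise = rng.poisson(np.maximum(counts, 1) * 0.001)
    return pd.DataFrame({"depth": depths, "count": counts + noise})
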