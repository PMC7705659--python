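"""Assembly/annotation summaries and k-mer genome-size estimation.

Shows the derived statistics of a chromosome-scale assembly report (N50,
anchored fraction, exons per gene) and the histogram peak-ratio estimator
recovering the size of a synthetic 264-Mb k-mer histogram.
"""

from wgdclock.stats import (
    annotation_stats_from_counts,
    assembly_stats,
    kmer_genome_size,
    n50_l50,
    percent,
    simulate_kmer_histogram,
)

# a toy scaffold set: two chromosomes + unplaced scaffolds
seqs = {"chr1": "ACGT" * 30_000, "chr2": "GGCTA" * 16_000,
        "scaf1": "AT" * 4_000, "scaf2": "GC" * 1_500}
s = assembly_stats(seqs, chromosome_ids=["chr1", "chr2"])
print(f"assembly: {s.n_scaffolds} scaffolds, {s.total_bp:,} bp, "
      f"N50 = {s.n50:,}, L50 = {s.l50}, GC = {s.gc_fraction:.2%}")
print(f"anchored to chromosomes: {s.anchored_pct}% of the assembly")

# the derived statistics a genome report prints, from its own counts
print(f"published-count arithmetic: anchored "
      f"{percent(174_586_151, 197_688_650)}%, genes on chromosomes "
      f"{annotation_stats_from_counts(25_813, 140_984, 25_295).pct_on_chromosomes}%, "
      f"exons/gene {round(140_984 / 25_813, 2)}")

hist = simulate_kmer_histogram(264_000_000, coverage=50.0, seed=7)
est = kmer_genome_size(hist)
print(f"k-mer estimator: error cutoff at depth {est['error_cutoff']}, "
      f"peak at {est['peak_depth']}x, genome size "
      f"{est['genome_size_bp'] / 1e6:.0f} Mb (built to 264 Mb)")
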