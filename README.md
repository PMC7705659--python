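# wgdclock

Synteny-based detection and molecular-clock dating of whole-genome
duplications (WGDs) for plant genome pairs, with an LTR-retrotransposon
insertion clock, subgenome retention/dominance tests, assembly summary
statistics — and a built-in simulator of genome pairs with known duplication
history so every stage can be validated against ground truth.

## Who this is for

Comparative genomicists working with a focal genome and a reference genome
(the motivating setting is a Brassicaceae pair: a focal species that
underwent a recent lineage-specific WGD on top of an older WGD shared with
the reference). The package reimplements, as a tested Python library, the
classic analysis chain:

1. **Homology & collinearity** — filter all-vs-all protein hits
   (e-value ≤ 1e-5), chain them into collinear blocks by dynamic programming
   on gene ranks (the MCScanX/ColinearScan stage), tabulate dotplot anchors.
2. **Ks estimation** — protein-guided codon alignment and Nei–Gojobori
   (1986) counting with Jukes–Cantor correction for every anchor pair:
   Ks = −(3/4)·ln(1 − (4/3)·ps).
3. **WGD dating** — lognormal mixture fitting of the Ks distribution (EM,
   BIC model selection), evolutionary-rate correction, and age conversion
   via **T = Ks / 2r** with neutral rate r = 8.22×10⁻⁹ /site/year.
4. **Rate correction** — with the focal and reference peaks of the *same*
   shared WGD at k_L and k_C, the relative rate is **r = (k_L − k_C)/k_C**
   and every focal peak (and the ortholog peak) is rescaled by
   **W_L = 1/(1+r)**, so ages are comparable across lineages with unequal
   substitution rates.
5. **LTR clock** — insertion age of an intact retrotransposon from the
   divergence d of its two LTRs: **T = d / 2μ**, μ = 7×10⁻⁹ /site/year
   (JC69 or K80 distances).
6. **Subgenome behaviour** — per-block gene retention against a reference
   genome (exact binomial test of singly-retained genes) and homoeolog
   expression dominance (Wilcoxon signed-rank on log2 ratios), both with
   Benjamini–Hochberg correction.
7. **Genome statistics** — N50/L50, GC, anchored fraction, exons per gene,
   and a k-mer-histogram genome-size estimator (volume / peak depth).

## Worked example

```python
from wgdclock.simulate import SimConfig
from wgdclock.pipeline import recover_wgd_ages

cfg = SimConfig(n_genes_ancestor=300, n_chromosomes=4,
                loss_rate=0.3, rate_asymmetry_r=0.3, seed=3)
res = recover_wgd_ages(cfg)
print(f"focal Ks peaks: {res.peaks_focal[0]:.3f}, {res.peaks_focal[1]:.3f}")
print(f"relative rate r = {res.correction.r:.3f}, W_L = {res.correction.W_L:.3f}")
print(f"specific WGD: {res.corrected_age_specific:.2f} Mya "
      f"(uncorrected {res.uncorrected_age_specific:.2f}, true {res.true_age_specific})")
print(f"shared WGD:   {res.corrected_age_shared:.2f} Mya "
      f"(uncorrected {res.uncorrected_age_shared:.2f}, true {res.true_age_shared})")
```

prints

```
focal Ks peaks: 0.490, 1.143
relative rate r = 0.331, W_L = 0.751
specific WGD: 22.38 Mya (uncorrected 29.79, true 22.99)
shared WGD:   52.23 Mya (uncorrected 69.52, true 52.01)
```

The simulated focal lineage evolves 30% faster than the reference, so the
uncorrected Ks peaks (0.490, 1.146) overstate both ages by roughly that
factor; pairing the larger focal peak with the reference genome's peak
measures r from the data, and the W_L-rescaled peaks date both duplications
within a few percent of the simulated truth. See `examples/` for one short
script per capability (synteny dotplots, NG86, LTR dating, subgenome tests,
assembly statistics).

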