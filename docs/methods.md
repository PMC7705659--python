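# Methods

## The dating model

Synonymous substitutions accumulate approximately neutrally, so the Ks value
of a duplicate gene pair clocks the time since its duplication, and the mode
of the Ks distribution of pairs created by one whole-genome duplication (WGD)
estimates the event's age via

    T = Ks / (2 r),        r = neutral substitution rate per site per year.

The default rate is 8.22e-9 /site/year, the Brassicaceae calibration used
throughout; it is a parameter everywhere it appears.

Lineages evolve at unequal rates. If the focal lineage L runs faster than a
reference lineage C, every Ks measured inside L is inflated by the same
factor, so its ages are biased high. The correction uses a WGD *shared* by
both lineages as an internal standard: with the shared event's peak at k_L
in the focal paralog distribution and at k_C in the reference distribution,

    r_rel = (k_L - k_C) / k_C,      W_L = 1 / (1 + r_rel),

and every focal peak — including the between-species ortholog peak — is
rescaled by W_L before conversion to time. By construction W_L·k_L = k_C
exactly; this identity is asserted in the tests. The correction assumes the
rate contrast is constant along the whole path since the shared event; its
accuracy for the younger event degrades gracefully if it is not.

## Simulator

`simulate.simulate_genome_pair` encodes the two-lineage scenario: one WGD
shared by L and C (default 52.01 Mya), a split (21.53 Mya), and an
L-specific WGD (22.99 Mya), with per-lineage rate asymmetry, fractionation,
inversions and translocations. The defaults are the study scenario's ages
and rates; `n_genes_ancestor` defaults to 2000 chromosome-partitioned genes,
a repository choice of convenient scale, not an empirical value.

Two conventions deserve explanation:

- **Specific WGD older than the split.** The default ages place the focal
  duplication (22.99 Mya) slightly before the split (21.53 Mya), as the
  radiative-divergence scenario implies. The simulator places the
  duplication on the focal stem at the split and backdates its divergence,
  so each duplicate pair carries 2·rate_L·t_specific substitutions per
  synonymous site regardless of the ordering.
- **Whole-path rate asymmetry.** Lineage L's synonymous divergence is
  (1 + r) times C's over the *entire* path since the shared WGD — the same
  assumption the correction makes — so that k_L = (1+r)·k_C holds for the
  shared event. The physically shared pre-split branch is simulated once at
  the base rate and L's excess over that stretch is added to L's post-split
  stem. The truth ledger records the exact path-implied Ks for every pair
  class, and the calibration test checks realized NG86 means against them.

Coding sequences are ATG + a body of codons from a family with fourfold-
degenerate third positions (Ala/Val/Thr/Ser/Pro/Gly) + TAA. Synonymous
evolution is a per-site Jukes–Cantor process on third positions at the
branch's synonymous rate; nonsynonymous evolution swaps the codon prefix to
another family member at relative rate omega (default 0.2). Within the
family every third-position change is synonymous and every prefix change is
nonsynonymous, so the synonymous clock is exact by construction and internal
stop codons cannot arise. The price is realism: simulated proteins use a
six-letter alphabet and uniform codon usage, so homology detection on them
is *harder* than on real proteins of equal divergence (fewer distinct
k-mers, composition-driven chance similarity), and Ka values are only
order-of-magnitude realistic. Passing tests therefore demonstrate the
pipeline's arithmetic and calibration, not BLAST-grade search sensitivity.

Fractionation deletes one random member of each most-recent-WGD duplicate
pair with probability `loss_rate` (default 0.3), independently per lineage;
rearrangements are applied after duplication and before loss, with
breakpoints at gene boundaries. Gene counts satisfy
ancestor × 2^(#WGDs) − losses exactly, and this is tested.

LTR elements are simulated as two initially identical copies (default 1 kb)
evolving independently under JC69 at mu (default 7e-9 /site/year), so a pair
of age t has expected divergence 2·mu·t. Expression matrices place subgenome
A `dominance_log2fc` log2 units above B around a shared per-pair baseline
(log2 expression ~ N(8, 1.5)) with Gaussian sample noise; three samples by
default, mirroring a three-tissue RNA-seq panel.

## Homology and collinearity

`score_homologs_builtin` is a deliberately simple all-vs-all scorer so the
pipeline runs without an external search tool: k-mer prefilter (8-mers;
threshold adapts from 2 shared k-mers for short proteins to 4 for long
ones), global alignment under BLOSUM62 with affine gaps (-10/-0.5), and two
acceptance rules — a surrogate e-value in Karlin–Altschul form with fixed
nominal parameters (lambda=0.267, K=0.041; a monotone transform of the
score, *not* comparable to any external tool's e-values), and a
bit-score-ratio-style floor: a hit must reach 35% of the smaller
self-alignment score. The ratio floor matters because global alignment of
unrelated, similarly composed sequences scores positively on composition
alone; on simulated data family members score ≥0.53 of self while unrelated
pairs stay ≤0.30. Externally produced 12-column hit tables are accepted at
face value and filtered at e ≤ 1e-5 (the study's threshold) with an optional
per-query cap.

Collinear blocks are maximal-scoring chains of hits on the (rank_A, rank_B)
plane, computed per chromosome pair and orientation by longest-path dynamic
programming: an edge joins hits with 0 < Δrank ≤ max_gap in both genomes
(consistent sign), costing gap_penalty·(ΔA + ΔB − 2). Chains are peeled off
best-first, removing their gene pairs, until none of at least
min_block_size anchors remains; each gene pair belongs to at most one
block. Defaults max_gap=25, min_block_size=5, gap_penalty=1 follow common
MCScanX practice; all are arguments. Tandem arrays (same genome, rank
distance ≤ 2, same partner) are collapsed to their best-scoring member
before chaining. Tie-breaks are lexicographic throughout, making block
detection deterministic. The DP is validated against exhaustive chain
enumeration on small random instances.

## NG86 Ka/Ks

Anchor pairs are codon-aligned by global protein alignment (BLOSUM62,
affine) back-translated codon-by-codon; gaps are whole codons. Counting
follows Nei–Gojobori (1986): per codon, each position contributes fractional
synonymous/nonsynonymous sites from its three possible changes, with
changes to stop codons excluded from numerator and denominator; differences
between codon pairs average synonymous/nonsynonymous steps over all minimal
mutational pathways with equal weights, excluding pathways through stops
(if every pathway is blocked — possible only in contrived cases — all
pathways are used with stop steps counted as nonsynonymous). Site counts
are averaged between the two sequences; this is the standard convention and
is fixed. Proportions are Jukes–Cantor corrected. Records are invalid when
fewer than 30 ungapped codons remain (a noise floor, adjustable), when no
synonymous sites exist, or when ps or pn reaches 3/4 (saturation). The
counting machinery is checked exactly against a brute-force pathway
enumeration oracle.

## Peak fitting and dating

Ks values are bounded to [0.005, 3.0] by default (saturation above, allelic
noise below; both adjustable) and fitted with Gaussian mixtures on log(Ks)
— lognormal components, since Ks is positive and right-skewed — by EM with
10 restarts from a fixed seed; the component count is chosen by BIC over
k = 1..4, and peak locations are reported as component medians exp(mu) on
the Ks scale. A KDE-local-maxima finder is provided as a cross-check. The
end-to-end driver (`pipeline.recover_wgd_ages`) uses scenario-informed
component counts instead of BIC: two components for the focal paralog
distribution (its two WGDs), one for the reference, and two for the
between-genome distribution — the anchor set there mixes true orthologs
with cross-subgenome pairs that coalesce at the shared WGD, and the
species-divergence peak is the lower component. Ages are kept at full
precision internally and rounded to two decimals only for display.

## LTR clock

Divergence between a retrotransposon's two LTRs is a p-distance over
ungapped aligned columns (global alignment when lengths differ), corrected
under K80 by default (transition/transversion aware) or JC69 on request —
the choice matters little below p ≈ 0.02 and the tests check the two agree
within 5% there. Insertion age is d/(2·mu). Elements whose alignment
exceeds 20% gaps are flagged low-confidence but still dated; saturated
distances are flagged and excluded from age profiles.

## Subgenome tests

Retention: per block, the split of genes retained in exactly one subgenome
is tested against 1:1 by a two-sided exact binomial test, with BH
correction across blocks and a pooled genome-wide test; the pooled retention
rate is identically the gene-count-weighted mean of block rates.
Dominance: per homoeolog pair, the mean over shared samples of
log2((A + 1)/(B + 1)); per block, a Wilcoxon signed-rank test of the ratios
against zero, BH across blocks; a block is called dominant only when q <
alpha (0.05) *and* the median ratio exceeds 1 log2 unit, and blocks with
fewer than 5 pairs are reported but never called (flagged underpowered).
The tests were chosen as assumption-light standards; alpha, the effect
floor, the pseudocount and the minimum block size are all arguments.

## Genome statistics

N50/L50 use the cumulative ≥ total/2 convention and are validated against a
brute-force oracle; GC excludes ambiguous bases; percentages are rounded
half-up to two decimals at presentation only. The k-mer genome-size
estimator is the simple peak-ratio method: error cutoff at the first local
minimum of count vs depth, homozygous peak as the argmax beyond it,
estimate = k-mer volume beyond the cutoff / peak depth. It is linear in
genome content and invariant to coverage, and recovers the size of a
synthetic Poisson histogram within 2%; only order-of-magnitude agreement is
claimed for real histograms, whose error structure is messier.

## Problem sizes and determinism

The validation suite runs the full pipeline at 1500 ancestor genes (the
scale at which both Ks peaks are well resolved), the calibration checks at
700, and unit fixtures at 60–300; the acceptance script uses the same
1500-gene scenario. Every stochastic component takes an explicit seed —
simulation through `SimConfig.seed`, mixture fitting through its own seed —
and identical seeds give bitwise-identical genomes, FASTA files and fitted
models.

## Known limitations

- The builtin homology scorer is a convenience, not a search engine: its
  seed sensitivity drops below ~65% protein identity for short genes, and
  its surrogate e-values are internally consistent but uncalibrated.
- NG86 with equal-weight pathways and JC correction is the classical
  estimator; no maximum-likelihood dN/dS, codon-frequency or ts/tv-weighted
  variants are provided.
- The rate correction supports one focal and one reference genome; no
  multi-species triangulation.
- Subgenome assignments are consumed as input (or simulation truth);
  ancestral-karyotype reconstruction is out of scope.
- Simulated data idealizes real genomes: no introns/UTRs, uniform codon
  usage, a six-letter protein alphabet, no transposon families, and
  fractionation independent of gene function.
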