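"""Codon alignment and NG86 against a brute-force enumeration oracle."""

import math

import numpy as np
import pytest

from oracles import oracle_ng86_counts
from wgdclock.ks import (
    CodonAlignment,
    PairSkipped,
    SENSE_CODONS,
    align_pair,
    jukes_cantor,
    ks_for_blocks,
    ks_for_pair,
    ng86,
)
from wgdclock.simulate import SimConfig, simulate_genome_pair
from wgdclock.synteny import CollinearBlock


def _aln(codons_a, codons_b, pair=("A", "B")):
    return CodonAlignment(pair=pair, codons_a=tuple(codons_a), codons_b=tuple(codons_b))


class TestAlignPair:
    def test_identical_cds_gapless(self):
        cds = "ATG" + "GCT" * 40 + "TAA"
        aln = align_pair(None, None, cds, cds)
        assert "---" not in aln.codons_a and "---" not in aln.codons_b
        assert aln.codons_a == aln.codons_b

    def test_manual_gap_backtranslation(self):
        # 5-codon protein vs the same with one residue deleted
        cds_a = "ATG" + "GCA" + "ACC" + "GGT" + "CCA"
        cds_b = "ATG" + "GCA" + "GGT" + "CCA"
        aln = align_pair(None, None, cds_a, cds_b)
        assert len(aln.codons_a) == 5
        assert aln.codons_a == ("ATG", "GCA", "ACC", "GGT", "CCA")
        assert aln.codons_b.count("---") == 1
        # the gap must fall on the deleted residue, keeping other codons intact
        kept = [c for c in aln.codons_b if c != "---"]
        assert kept == ["ATG", "GCA", "GGT", "CCA"]

    def test_internal_stop_rejected(self):
        bad = "ATG" + "TAA" + "GCT" * 40 + "TAA"
        with pytest.raises(PairSkipped, match="internal stop"):
            align_pair(None, None, bad, bad)

    def test_protein_mismatch_rejected(self):
        cds = "ATG" + "GCT" * 40 + "TAA"
        with pytest.raises(PairSkipped, match="translate"):
            align_pair("M" + "A" * 39 + "V", None, cds, cds)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(PairSkipped):
            align_pair(None, None, "ATGGC", "ATGGC")


class TestNG86:
    def test_identical_sequences_zero(self):
        codons = ["ATG"] + ["GCT"] * 40
        rec = ng86(_aln(codons, codons))
        assert rec.valid
        assert rec.Sd == rec.Nd == 0.0
        assert rec.Ka == rec.Ks == 0.0

    def test_symmetry_under_swap(self, rng):
        codons_a = [SENSE_CODONS[i] for i in rng.integers(0, 61, 50)]
        codons_b = [SENSE_CODONS[i] for i in rng.integers(0, 61, 50)]
        r1 = ng86(_aln(codons_a, codons_b))
        r2 = ng86(_aln(codons_b, codons_a))
        for field in ("S", "N", "Sd", "Nd", "ps", "pn", "Ks", "Ka"):
            v1, v2 = getattr(r1, field), getattr(r2, field)
            assert (v1 == v2) or (math.isnan(v1) and math.isnan(v2)), field

    def test_single_codon_glu_synonymous_change(self):
        """GAA vs GAG: one synonymous difference, a third of a synonymous site.

        With S = 1/3 the proportion ps = 3 exceeds the JC domain, so the
        record cannot carry a finite Ks and is reported invalid (it is also
        far below the minimum-codon gate).
        """
        rec = ng86(_aln(["GAA"], ["GAG"]), min_codons=1)
        s, n, sd, nd = oracle_ng86_counts(["GAA"], ["GAG"])
        assert rec.Sd == sd == 1.0
        assert rec.Nd == nd == 0.0
        assert rec.S == pytest.approx(s) and s == pytest.approx(1 / 3)
        assert not rec.valid

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        """S, N, Sd, Nd equal the pathway-enumeration oracle exactly."""
        for _ in range(500):
            n = int(rng.integers(1, 11))
            ca = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
            cb = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
            rec = ng86(_aln(ca, cb), min_codons=1)
            s, n_, sd, nd = oracle_ng86_counts(ca, cb)
            assert rec.S == pytest.approx(s, abs=1e-9)
            assert rec.N == pytest.approx(n_, abs=1e-9)
            assert rec.Sd == pytest.approx(sd, abs=1e-9)
            assert rec.Nd == pytest.approx(nd, abs=1e-9)

    def test_site_counts_sum_to_three_per_codon(self, rng):
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, 60)]
        rec = ng86(_aln(codons, codons))
        assert rec.S + rec.N == pytest.approx(3 * 60, abs=1e-6)

    def test_saturation_flagged(self):
        # fourfold-degenerate third positions maximally shuffled
        ca = ["GGA"] * 39
        cb = ["GGG", "GGC", "GGT"] * 13
        rec = ng86(_aln(ca, cb))
        assert not rec.valid
        assert rec.reason == "saturated"

    def test_short_alignment_invalid(self):
        rec = ng86(_aln(["GCT"] * 10, ["GCT"] * 10))
        assert not rec.valid and rec.reason == "too_short"

    def test_jc_small_distance_limit(self):
        ps = 1e-4
        assert jukes_cantor(ps) / ps == pytest.approx(1.0, abs=1e-3)

    def test_gap_and_ambiguous_columns_dropped(self):
        ca = ["GCT"] * 35 + ["---", "GCN"]
        cb = ["GCT"] * 35 + ["GCA", "GCT"]
        rec = ng86(_aln(ca, cb))
        assert rec.n_codons == 35


class TestKsForBlocks:
    def _block(self, pairs):
        return CollinearBlock(
            block_id="b0001",
            seq_pair=("A1", "B1"),
            anchors=[(a, b, i, i) for i, (a, b) in enumerate(pairs)],
            orientation="same",
            score=1.0,
        )

    def test_identical_pairs_median_zero(self):
        cds = {f"g{i}": "ATG" + "GCT" * 40 + "TAA" for i in range(10)}
        block = self._block([(f"g{i}", f"g{i+5}") for i in range(5)])
        records, per_block = ks_for_blocks([block], cds)
        assert len(records) == 5
        assert per_block.loc[0, "median_ks"] == 0.0

    def test_missing_cds_counted_not_fatal(self):
        cds = {"g0": "ATG" + "GCT" * 40 + "TAA"}
        block = self._block([("g0", "gX")])
        records, _ = ks_for_blocks([block], cds)
        assert records.loc[0, "reason"] == "missing_cds"
        assert not records.loc[0, "valid"]

    def test_row_count_conservation(self, small_pair):
        genes_l, _, truth = small_pair
        cds = {g.gene_id: g.cds for g in genes_l}
        pairs = [(p.gene_a, p.gene_b) for p in truth.pairs("specific")[:20]]
        block = self._block(pairs)
        records, per_block = ks_for_blocks([block], cds)
        assert len(records) == 20
        assert per_block.loc[0, "n_anchors"] == 20

    def test_specific_wgd_block_median_near_truth(self, small_pair, small_config):
        genes_l, _, truth = small_pair
        cds = {g.gene_id: g.cds for g in genes_l}
        block = self._block([(p.gene_a, p.gene_b) for p in truth.pairs("specific")])
        _, per_block = ks_for_blocks([block], cds)
        assert per_block.loc[0, "median_ks"] == pytest.approx(
            truth.expected_ks_specific, abs=0.05
        )


class TestMonotonicity:
    def test_mean_ks_increases_with_age(self):
        means = []
        for age in (5.0, 15.0, 30.0):
            cfg = SimConfig(
                n_genes_ancestor=60,
                n_chromosomes=2,
                shared_wgd_age_mya=60.0,
                specific_wgd_age_mya=age,
                split_age_mya=30.0,
                loss_rate=0.0,
                n_inversions=0,
                n_translocations=0,
                seed=13,
            )
            genes_l, _, truth = simulate_genome_pair(cfg)
            cds = {g.gene_id: g.cds for g in genes_l}
            vals = [
                ks_for_pair(cds[p.gene_a], cds[p.gene_b]).Ks
                for p in truth.pairs("specific")[:60]
            ]
            means.append(np.nanmean(vals))
        assert means[0] < means[1] < means[2]
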